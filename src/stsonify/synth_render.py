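"""Additive tone synthesis and WAV rendering of a tone-event schedule.

Each tone is a phase-aligned sum of N harmonics,

    s(t) = (1/N) * sum_{n=1..N} cos(2*pi*n*f*t - n*pi/2),

shaped by an exponential fade-out envelope

    w_{c,d}(t) = 1 - (1 - exp(c*t/d)) / (1 - exp(c)),

where c is the curve (negative: percussive, fast initial decay; positive:
sustained, late decay), d the duration, and scaled by 10**(level_db/20)
with level_db relative to digital full scale (0 dB = amplitude 1).
Events are mixed additively at their onsets; samples beyond +-1 are
hard-clipped (and counted) rather than normalized so that level
arithmetic stays exact.
"""

from __future__ import annotations

import logging
import math
import wave
from dataclasses import dataclass

import numpy as np

from .scheduler import Schedule, ToneEvent

__all__ = [
    "AudioBuffer",
    "envelope",
    "synth_tone",
    "render",
    "write_wav",
    "read_wav",
    "sonify_to_wav",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 44100


@dataclass
class AudioBuffer:
    """Mono PCM buffer with samples in [-1, 1]."""

    sample_rate: float
    samples: np.ndarray
    clipped_samples: int = 0

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


def envelope(t, c: float, d: float):
    """Fade-out weight w_{c,d}(t) = 1 - (1 - e^{c t/d}) / (1 - e^c).

    Equals 1 at t = 0 and 0 at t = d, strictly decreasing in between for
    any c != 0; the c -> 0 limit is the linear ramp 1 - t/d.
    """
    if d <= 0:
        raise ValueError("duration d must be positive")
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > d)):
        raise ValueError("t must lie in [0, d]")
    if abs(c) < 1e-9:  # analytic limit; avoids 1 - e^c underflow
        out = 1.0 - t / d
    else:
        out = 1.0 - (1.0 - np.exp(c * t / d)) / (1.0 - np.exp(c))
    return out if out.shape else float(out)


def synth_tone(event: ToneEvent, sample_rate: float = DEFAULT_SAMPLE_RATE
               ) -> np.ndarray:
    """Render one tone to ``round(duration * sample_rate)`` samples."""
    top_harmonic = event.n_harmonics * event.frequency_hz
    if sample_rate < 4 * top_harmonic:
        raise ValueError(
            f"sample rate {sample_rate} Hz too low for harmonic at "
            f"{top_harmonic:.1f} Hz (need >= {4 * top_harmonic:.0f} Hz)")
    n = round(event.duration_s * sample_rate)
    t = np.arange(n) / sample_rate
    osc = np.zeros(n)
    for h in range(1, event.n_harmonics + 1):
        osc += np.cos(2.0 * np.pi * h * event.frequency_hz * t
                      - h * np.pi / 2.0)
    osc /= event.n_harmonics
    gain = 10.0 ** (event.level_db / 20.0)
    return gain * envelope(t, event.envelope_curve, event.duration_s) * osc


def render(schedule: Schedule, sample_rate: float = DEFAULT_SAMPLE_RATE
           ) -> AudioBuffer:
    """Additively mix all events; hard-clip to [-1, 1] and log clip count."""
    n_total = math.ceil(schedule.total_duration_s * sample_rate)
    mix = np.zeros(n_total)
    for event in schedule.events:
        start = round(event.onset_s * sample_rate)
        tone = synth_tone(event, sample_rate)
        stop = min(start + len(tone), n_total)
        mix[start:stop] += tone[:stop - start]
    clipped = int(np.count_nonzero(np.abs(mix) > 1.0))
    if clipped:
        logger.warning("hard-clipped %d samples exceeding full scale",
                       clipped)
        mix = np.clip(mix, -1.0, 1.0)
    return AudioBuffer(sample_rate=sample_rate, samples=mix,
                       clipped_samples=clipped)


def write_wav(buffer: AudioBuffer, path) -> None:
    """Write 16-bit PCM mono RIFF/WAV (full scale 1.0 -> 32767)."""
    pcm = np.round(np.clip(buffer.samples, -1.0, 1.0) * 32767.0
                   ).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(round(buffer.sample_rate))
        wf.writeframes(pcm.tobytes())


def read_wav(path) -> AudioBuffer:
    """Read a 16-bit PCM mono WAV back into [-1, 1] floats."""
    with wave.open(str(path), "rb") as wf:
        if wf.getnchannels() != 1 or wf.getsampwidth() != 2:
            raise ValueError("expected 16-bit PCM mono WAV")
        sample_rate = wf.getframerate()
        pcm = np.frombuffer(wf.readframes(wf.getnframes()), dtype="<i2")
    return AudioBuffer(sample_rate=float(sample_rate),
                       samples=pcm.astype(float) / 32767.0)


def sonify_to_wav(schedule: Schedule, path,
                  sample_rate: float = DEFAULT_SAMPLE_RATE) -> AudioBuffer:
    """Render a schedule and write it to *path*; returns the buffer."""
    buffer = render(schedule, sample_rate)
    write_wav(buffer, path)
    return buffer


def plot_spectrogram(buffer: AudioBuffer, path=None, fmax: float = 2500.0):
    """Spectrogram figure of a rendered buffer (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import scipy.signal

    f, t, sxx = scipy.signal.spectrogram(buffer.samples, buffer.sample_rate,
                                         nperseg=2048, noverlap=1536)
    keep = f <= fmax
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.pcolormesh(t, f[keep], 10 * np.log10(sxx[keep] + 1e-12),
                  shading="gouraud")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("frequency [Hz]")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
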