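"""Tone-event scheduling for the grouped-lead-scan and arpeggio designs.

The grouped-lead-scan design plays a short QRS reference tone on every
heartbeat and, once per cycle of ``set_separation_beats`` heartbeats, scans
the 12 leads as two six-tone groups: the limb group anchored at the cycle's
first beat and the precordial group ``stride_beats`` later, with a constant
inter-tone interval dt that does not depend on the heart rate.

The arpeggio design (an earlier, denser concept) instead plays all 12
leads as a rapid scale run locked to every heartbeat; non-isoelectric
leads are played longer, louder and sharper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .leads import STANDARD_ORDER
from .mapping import (
    MappingConfig,
    order_leads,
    pitch_offset,
    semitone_to_frequency,
    tone_params,
)
from .synthetic_ecg import STProfile

__all__ = [
    "ToneEvent",
    "Schedule",
    "build_schedule",
    "build_arpeggio_schedule",
    "schedule_to_frame",
    "write_schedule_csv",
    "DIATONIC_ARPEGGIO_SCALE",
    "PENTATONIC_ARPEGGIO_SCALE",
]

logger = logging.getLogger(__name__)

#: 12-tone arpeggio scales: major scale with the precordial half transposed
#: up one octave, and a pentatonic run.
DIATONIC_ARPEGGIO_SCALE = (0, 2, 4, 5, 7, 9, 12, 14, 16, 17, 19, 21)
PENTATONIC_ARPEGGIO_SCALE = (0, 2, 4, 7, 9, 12, 14, 16, 19, 21, 24, 26)

# QRS reference-tone rendering (configurable stand-ins; the design only
# fixes its pitch at f0).
QRS_TONE_DURATION_S = 0.030
QRS_TONE_N_HARMONICS = 2
QRS_TONE_CURVE = -3.0

# Arpeggio emphasis for non-isoelectric leads: duration x2, +10 dB.
ARPEGGIO_TONE_DURATION_S = 0.035
ARPEGGIO_LONG_FACTOR = 2.0
ARPEGGIO_LOUD_BOOST_DB = 10.0


@dataclass(frozen=True)
class ToneEvent:
    """A single renderable tone."""

    onset_s: float
    frequency_hz: float
    duration_s: float
    level_db: float
    n_harmonics: int
    envelope_curve: float
    kind: str  # "qrs" or "st_tone"
    label: str

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValueError("onset_s must be non-negative")
        if self.duration_s <= 0 or self.frequency_hz <= 0:
            raise ValueError("duration and frequency must be positive")


@dataclass(frozen=True)
class Schedule:
    """Tone events sorted by onset plus the timeline extent."""

    events: tuple[ToneEvent, ...]
    total_duration_s: float
    beat_period_s: float

    def __post_init__(self):
        onsets = [e.onset_s for e in self.events]
        if any(a > b for a, b in zip(onsets, onsets[1:])):
            raise ValueError("events must be sorted by onset")
        if self.events:
            last_end = max(e.onset_s + e.duration_s for e in self.events)
            if self.total_duration_s < last_end:
                raise ValueError("total_duration_s must cover the last event")

    @property
    def st_tones(self) -> tuple[ToneEvent, ...]:
        return tuple(e for e in self.events if e.kind == "st_tone")

    @property
    def qrs_tones(self) -> tuple[ToneEvent, ...]:
        return tuple(e for e in self.events if e.kind == "qrs")


def _qrs_event(onset_s: float, cfg: MappingConfig) -> ToneEvent:
    return ToneEvent(
        onset_s=onset_s,
        frequency_hz=cfg.f0,
        duration_s=QRS_TONE_DURATION_S,
        level_db=cfg.base_level_db,
        n_harmonics=QRS_TONE_N_HARMONICS,
        envelope_curve=QRS_TONE_CURVE,
        kind="qrs",
        label="QRS",
    )


def _st_event(onset_s: float, label: str, value: float,
              cfg: MappingConfig) -> ToneEvent:
    params = tone_params(value, cfg)
    freq = semitone_to_frequency(pitch_offset(value, cfg), cfg.f0)
    return ToneEvent(
        onset_s=onset_s,
        frequency_hz=freq,
        duration_s=params.duration_s,
        level_db=params.level_db,
        n_harmonics=params.n_harmonics,
        envelope_curve=params.envelope_curve,
        kind="st_tone",
        label=label,
    )


def build_schedule(profile: STProfile, cfg: MappingConfig | None = None,
                   bpm: float = 80.0, n_cycles: int = 1) -> Schedule:
    """Grouped-lead-scan schedule: QRS on every beat, 12 ST tones per cycle.

    Cycle j starts at beat ``j * set_separation_beats``; its six limb-group
    tones start exactly at that beat and its six precordial tones at the
    beat ``stride_beats`` later, both with dt spacing.  Beats are at
    nominal positions b * 60/bpm (the study used a constant heart rate).
    """
    cfg = cfg or MappingConfig()
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if bpm <= 0:
        raise ValueError("bpm must be positive")
    beat_period = 60.0 / bpm
    if 6 * cfg.dt_s > beat_period * cfg.stride_beats:
        logger.warning(
            "limb group (6 x dt = %.3f s) outlasts the stride gap (%.3f s); "
            "groups will overlap", 6 * cfg.dt_s,
            beat_period * cfg.stride_beats)

    n_beats = n_cycles * cfg.set_separation_beats
    events = [_qrs_event(b * beat_period, cfg) for b in range(n_beats)]

    for j in range(n_cycles):
        anchor_beat = j * cfg.set_separation_beats
        seq = order_leads(profile, cfg.channel_mode)
        limb_start = anchor_beat * beat_period
        prec_start = (anchor_beat + cfg.stride_beats) * beat_period
        for i, tone in enumerate(seq.limb_group):
            events.append(_st_event(limb_start + i * cfg.dt_s,
                                    tone.label, tone.value, cfg))
        for i, tone in enumerate(seq.precordial_group):
            events.append(_st_event(prec_start + i * cfg.dt_s,
                                    tone.label, tone.value, cfg))

    events.sort(key=lambda e: (e.onset_s, e.kind, e.label))
    total = max(n_beats * beat_period,
                max(e.onset_s + e.duration_s for e in events))
    return Schedule(events=tuple(events), total_duration_s=total,
                    beat_period_s=beat_period)


def build_arpeggio_schedule(profile: STProfile,
                            scale=DIATONIC_ARPEGGIO_SCALE,
                            bpm: float = 80.0, dt_s: float = 0.040,
                            n_beats: int = 3, theta: float = 0.1,
                            cfg: MappingConfig | None = None) -> Schedule:
    """Heartbeat-locked arpeggio: 12 scale tones per beat in standard order.

    Tone i sounds at ``i * dt_s`` after the beat with pitch ``scale[i]``
    semitones above f0.  Leads with |st| > theta play twice as long and
    10 dB louder; timbre follows the sign of st (2/4/8 harmonics for
    suppressed/isoelectric/elevated).
    """
    cfg = cfg or MappingConfig()
    if len(scale) != 12:
        raise ValueError(f"arpeggio scale needs 12 entries, got {len(scale)}")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    beat_period = 60.0 / bpm

    events = []
    for b in range(n_beats):
        t0 = b * beat_period
        events.append(_qrs_event(t0, cfg))
        for i, lead in enumerate(STANDARD_ORDER):
            st = profile[lead]
            emphasized = abs(st) > theta
            if st < -theta:
                n_harm = 2      # dull: suppressed
            elif st > theta:
                n_harm = 8      # sharp: elevated
            else:
                n_harm = 4      # medium: isoelectric
            events.append(ToneEvent(
                onset_s=t0 + i * dt_s,
                frequency_hz=semitone_to_frequency(scale[i], cfg.f0),
                duration_s=ARPEGGIO_TONE_DURATION_S *
                (ARPEGGIO_LONG_FACTOR if emphasized else 1.0),
                level_db=cfg.base_level_db +
                (ARPEGGIO_LOUD_BOOST_DB if emphasized else 0.0),
                n_harmonics=n_harm,
                envelope_curve=QRS_TONE_CURVE,
                kind="st_tone",
                label=lead,
            ))

    events.sort(key=lambda e: (e.onset_s, e.kind, e.label))
    total = max(n_beats * beat_period,
                max(e.onset_s + e.duration_s for e in events))
    return Schedule(events=tuple(events), total_duration_s=total,
                    beat_period_s=beat_period)


def schedule_to_frame(schedule: Schedule) -> pd.DataFrame:
    """Event table with one row per tone, sorted by onset."""
    return pd.DataFrame([{
        "onset_s": e.onset_s,
        "kind": e.kind,
        "label": e.label,
        "frequency_hz": e.frequency_hz,
        "duration_s": e.duration_s,
        "level_db": e.level_db,
        "n_harmonics": e.n_harmonics,
        "curve": e.envelope_curve,
    } for e in schedule.events])


def write_schedule_csv(schedule: Schedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)
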