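"""Synthetic 12-lead ECG generation with controllable per-lead ST offset.

The sonification pipeline needs ECG input whose ground truth is known
exactly.  This module generates 12-lead recordings built from a stylized
beat template — Gaussian-windowed P and T bumps, a piecewise-linear QRS
spike with small Q/S deflections, and a flat ST plateau between the J point
and the T-wave onset — tiled at a fixed heart rate with optional additive
Gaussian noise.  It is the simplest morphology that exercises every stage
of the feature extractor, not a physiological model.

Seven named ST-profile fixtures cover the study conditions: isoelectric
(IE) plus anterior/inferior infarction at weak/moderate/severe grades.
Anterior conditions elevate V1-V4 with reciprocal inferior suppression;
inferior conditions elevate II, III, aVF with reciprocal lateral
suppression.  Severity places affected leads in the moderate (0.1, 0.2] mV
or strong (> 0.2 mV) band; every fixture value keeps a >= 0.03 mV margin
from the 0.1/0.2 mV category thresholds so that 5-level category recovery
is robust to measurement noise.  The numeric values are this package's own
documented stand-ins for simulator output, not published data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .leads import STANDARD_ORDER, validate_lead_names

__all__ = [
    "STProfile",
    "BeatMorphology",
    "ECGRecording",
    "CONDITIONS",
    "make_st_profile",
    "synthesize_beat",
    "generate_recording",
    "write_recording_csv",
    "read_recording_csv",
    "write_recording_npz",
    "read_recording_npz",
    "fixture_manifest",
    "write_fixture_manifest",
]


@dataclass(frozen=True)
class STProfile:
    """A 12-element vector of ST elevations in mV, keyed by lead name.

    Positive values are elevations, negative values suppressions, zero is
    isoelectric.
    """

    values: dict[str, float]

    def __post_init__(self):
        validate_lead_names(self.values)
        for lead, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite ST value for lead {lead}: {v}")

    def __getitem__(self, lead: str) -> float:
        return self.values[lead]

    def as_vector(self, order=STANDARD_ORDER) -> np.ndarray:
        return np.array([self.values[k] for k in order], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {k: float(self.values[k]) for k in STANDARD_ORDER}

    @classmethod
    def from_dict(cls, d) -> "STProfile":
        return cls({str(k): float(v) for k, v in d.items()})


#: The seven study conditions.
CONDITIONS = (
    "IE",
    "anterior-weak",
    "anterior-moderate",
    "anterior-severe",
    "inferior-weak",
    "inferior-moderate",
    "inferior-severe",
)

# Fixture ST vectors (mV).  Leads omitted from a row are 0.0.
_FIXTURE_NONZERO: dict[str, dict[str, float]] = {
    "IE": {},
    "anterior-weak": {
        "V1": 0.05, "V2": 0.07, "V3": 0.07, "V4": 0.05,
        "I": 0.03, "aVL": 0.03,
        "II": -0.03, "III": -0.05, "aVF": -0.05,
    },
    "anterior-moderate": {
        "V1": 0.13, "V2": 0.16, "V3": 0.16, "V4": 0.13,
        "I": 0.05, "aVL": 0.05,
        "II": -0.05, "III": -0.13, "aVF": -0.13,
    },
    "anterior-severe": {
        "V1": 0.24, "V2": 0.30, "V3": 0.30, "V4": 0.24, "V5": 0.13,
        "I": 0.05, "aVL": 0.05,
        "II": -0.13, "III": -0.16, "aVF": -0.16,
    },
    "inferior-weak": {
        "II": 0.05, "III": 0.07, "aVF": 0.07,
        "I": -0.03, "aVL": -0.05,
    },
    "inferior-moderate": {
        "II": 0.13, "III": 0.16, "aVF": 0.16,
        "I": -0.05, "aVL": -0.13, "V1": -0.05,
    },
    "inferior-severe": {
        "II": 0.24, "III": 0.30, "aVF": 0.30,
        "I": -0.13, "aVL": -0.16, "V1": -0.05, "V2": -0.05,
    },
}


def make_st_profile(condition: str) -> STProfile:
    """Return the fixed ST-profile fixture for a named study condition.

    ``IE`` is all zeros.  Affected leads of "severe" conditions exceed
    0.2 mV in magnitude, "moderate" ones lie in (0.1, 0.2] mV, "weak" ones
    stay at or below 0.1 mV; all values keep >= 0.03 mV clearance from the
    0.1/0.2 mV thresholds.
    """
    if condition not in _FIXTURE_NONZERO:
        raise ValueError(
            f"unknown condition {condition!r}; valid names: {list(CONDITIONS)}"
        )
    values = {k: 0.0 for k in STANDARD_ORDER}
    values.update(_FIXTURE_NONZERO[condition])
    return STProfile(values)


@dataclass(frozen=True)
class BeatMorphology:
    """Shape parameters of one synthetic beat.

    Amplitudes are in mV, widths in seconds, onsets as fractions of the RR
    interval.  Within one beat the P wave precedes the QRS complex, which
    precedes the ST plateau (J point to T onset), which precedes the T wave.
    """

    p_amplitude: float = 0.15
    qrs_amplitude: float = 1.0
    t_amplitude: float = 0.30
    st_offset: float = 0.0
    p_width: float = 0.09
    qrs_width: float = 0.07
    t_width: float = 0.16
    p_onset_frac: float = 0.02
    qrs_onset_frac: float = 0.15
    t_onset_frac: float = 0.55

    # Q and S deflections relative to the QRS width / R amplitude.
    _Q_FRAC = 0.15
    _R_FRAC = 0.30
    _S_FRAC = 0.45
    _Q_DEPTH = 0.10
    _S_DEPTH = 0.15

    def __post_init__(self):
        if min(self.p_width, self.qrs_width, self.t_width) <= 0:
            raise ValueError("component widths must be positive")

    def r_apex_offset_s(self, rr_s: float) -> float:
        """Time of the R apex from the start of the beat."""
        return self.qrs_onset_frac * rr_s + self._R_FRAC * self.qrs_width

    def j_point_s(self, rr_s: float) -> float:
        """Time of the J point (end of the QRS complex) from beat start."""
        return self.qrs_onset_frac * rr_s + self.qrs_width

    def st_plateau_s(self, rr_s: float) -> tuple[float, float]:
        """The [J point, T onset) interval holding the flat ST plateau."""
        return self.j_point_s(rr_s), self.t_onset_frac * rr_s


def _raised_cosine(t: np.ndarray, onset: float, width: float,
                   amplitude: float) -> np.ndarray:
    """Compact bump: zero outside [onset, onset+width], peak at its centre."""
    out = np.zeros_like(t)
    mask = (t >= onset) & (t <= onset + width)
    out[mask] = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi *
                                                (t[mask] - onset) / width))
    return out


def synthesize_beat(morph: BeatMorphology, rr_s: float,
                    sample_rate: float) -> np.ndarray:
    """Render one beat of ``round(rr_s * sample_rate)`` samples in mV.

    The baseline outside the P/QRS/ST/T supports is exactly 0 mV and the ST
    plateau between the J point and the T onset equals ``morph.st_offset``.
    """
    if rr_s <= 0 or sample_rate <= 0:
        raise ValueError("rr_s and sample_rate must be positive")
    if sample_rate < 100:
        raise ValueError("sample_rate must be at least 100 Hz")
    if rr_s <= morph.p_width + morph.qrs_width + morph.t_width:
        raise ValueError("rr_s must exceed the sum of component widths")

    p_on = morph.p_onset_frac * rr_s
    q_on = morph.qrs_onset_frac * rr_s
    t_on = morph.t_onset_frac * rr_s
    j = morph.j_point_s(rr_s)
    if not (p_on + morph.p_width <= q_on and j <= t_on
            and t_on + morph.t_width <= rr_s):
        raise ValueError(
            "beat components overlap at this RR interval: require "
            "P < QRS < ST plateau < T within one beat"
        )

    n = round(rr_s * sample_rate)
    t = np.arange(n) / sample_rate
    x = _raised_cosine(t, p_on, morph.p_width, morph.p_amplitude)
    x += _raised_cosine(t, t_on, morph.t_width, morph.t_amplitude)

    # Piecewise-linear QRS: 0 -> Q dip -> R apex -> S dip -> st_offset at J.
    a = morph.qrs_amplitude
    w = morph.qrs_width
    knots_t = np.array([q_on, q_on + morph._Q_FRAC * w, q_on + morph._R_FRAC * w,
                        q_on + morph._S_FRAC * w, j])
    knots_v = np.array([0.0, -morph._Q_DEPTH * a, a, -morph._S_DEPTH * a,
                        morph.st_offset])
    qrs_mask = (t >= q_on) & (t < j)
    x[qrs_mask] = np.interp(t[qrs_mask], knots_t, knots_v)

    # Flat ST plateau from the J point up to (excluding) the T onset.
    x[(t >= j) & (t < t_on)] = morph.st_offset
    return x


@dataclass
class ECGRecording:
    """12 named lead signals in mV at a fixed sampling rate."""

    sample_rate: float
    leads: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        validate_lead_names(self.leads)
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) != 1:
            raise ValueError(f"lead signals have unequal lengths: {lengths}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.leads.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def as_matrix(self, order=STANDARD_ORDER) -> np.ndarray:
        """(n_samples, 12) matrix of leads in the given column order."""
        return np.column_stack([self.leads[k] for k in order])


def generate_recording(profile: STProfile, bpm: float = 80.0,
                       duration_s: float = 10.0, sample_rate: float = 500.0,
                       noise_sd: float = 0.0, seed: int = 0,
                       morphology: BeatMorphology | None = None
                       ) -> ECGRecording:
    """Tile beats at a fixed rate into a 12-lead recording.

    Every lead uses the same beat morphology except for its ST offset taken
    from *profile*, so R spikes are time-aligned across leads.  Gaussian
    noise of standard deviation *noise_sd* (mV) is added i.i.d. per sample
    per lead.  Identical arguments give bit-identical output.
    """
    if not 30 <= bpm <= 220:
        raise ValueError(f"bpm must be in [30, 220], got {bpm}")
    rr_s = 60.0 / bpm
    if duration_s <= rr_s:
        raise ValueError("duration_s must exceed one beat period")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    morph = morphology if morphology is not None else BeatMorphology()

    n_total = round(duration_s * sample_rate)
    rng = np.random.default_rng(seed)
    leads: dict[str, np.ndarray] = {}
    for lead in STANDARD_ORDER:
        beat = synthesize_beat(replace(morph, st_offset=profile[lead]),
                               rr_s, sample_rate)
        reps = int(np.ceil(n_total / len(beat)))
        x = np.tile(beat, reps)[:n_total]
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, n_total)
        leads[lead] = x

    lo, hi = morph.st_plateau_s(rr_s)
    meta = {
        "bpm": bpm,
        "rr_s": rr_s,
        "noise_sd": noise_sd,
        "seed": seed,
        "n_complete_beats": int(np.floor(duration_s / rr_s)),
        "r_apex_offset_s": morph.r_apex_offset_s(rr_s),
        # ST plateau location relative to the R apex, as fractions of RR —
        # the window the extractor's median should target.
        "st_plateau_frac_from_r": (
            (lo - morph.r_apex_offset_s(rr_s)) / rr_s,
            (hi - morph.r_apex_offset_s(rr_s)) / rr_s,
        ),
    }
    return ECGRecording(sample_rate=sample_rate, leads=leads, meta=meta)


# ---------------------------------------------------------------------------
# Recording I/O: delimited text (time column + 12 lead columns, header row
# with lead names) and a compact binary container.

def write_recording_csv(rec: ECGRecording, path) -> None:
    t = np.arange(rec.n_samples) / rec.sample_rate
    df = pd.DataFrame({"time_s": t})
    for lead in STANDARD_ORDER:
        df[lead] = rec.leads[lead]
    df.to_csv(path, index=False)


def read_recording_csv(path) -> ECGRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("recording file must have a 'time_s' column")
    validate_lead_names(c for c in df.columns if c != "time_s")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("recording too short to infer the sampling rate")
    sample_rate = 1.0 / float(np.median(np.diff(t)))
    leads = {k: df[k].to_numpy(dtype=float) for k in STANDARD_ORDER}
    return ECGRecording(sample_rate=round(sample_rate, 6), leads=leads)


def write_recording_npz(rec: ECGRecording, path) -> None:
    np.savez_compressed(path, sample_rate=rec.sample_rate,
                        **{k: rec.leads[k] for k in STANDARD_ORDER})


def read_recording_npz(path) -> ECGRecording:
    with np.load(path) as data:
        leads = {k: data[k] for k in STANDARD_ORDER}
        return ECGRecording(sample_rate=float(data["sample_rate"]),
                            leads=leads)


def fixture_manifest() -> dict[str, dict[str, float]]:
    """All seven condition fixtures as a plain mapping."""
    return {cond: make_st_profile(cond).to_dict() for cond in CONDITIONS}


def write_fixture_manifest(path, fmt: str = "yaml") -> None:
    manifest = fixture_manifest()
    with open(path, "w") as fh:
        if fmt == "yaml":
            yaml.safe_dump(manifest, fh, sort_keys=False)
        elif fmt == "json":
            json.dump(manifest, fh, indent=2)
        else:
            raise ValueError(f"unknown manifest format {fmt!r}")
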