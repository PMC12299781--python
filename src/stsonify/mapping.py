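"""Parameter mapping from ST elevation to pitch, level, duration and timbre.

The sonification anchors every pitch to the QRS tone at f0 (554 Hz by
default) and expresses ST elevation as a semitone offset from it, so a
healthy (isoelectric) lead sounds at the reference pitch and deviations
move up (elevation) or down (suppression).  Six pitch-mapping modes are
provided:

``continuous``
    linear map of the clamped ST value from the source interval
    (+-0.4 mV) onto +-7 semitones (a musical fifth down/up);
``chromatic``
    the continuous result rounded to whole semitones;
``diatonic``
    index into a fixed 12-note two-octave scale table;
``five_state``
    five categories split at +-theta1 and +-theta2, mapped through a
    semitone table (study default [-8, -5, 0, +4, +7]);
``five_state_dissonant``
    as five_state but with dissonant extremes ([-11, -5, 0, +4, +8]);
``tristate``
    three categories at -5 / 0 / +7 semitones (fourth below, reference,
    fifth above).

Frequencies follow equal temperament: frequency(k) = f0 * 2**(k/12).
Tone duration, dB boost, harmonic count and envelope curve are stepped
over the same +-theta1/+-theta2 bands.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, asdict

import yaml

from .leads import (
    CABRERA_LIMB_ORDER,
    COUNTERCLOCKWISE_LIMB_ORDER,
    PRECORDIAL_ORDER,
)
from .synthetic_ecg import STProfile

__all__ = [
    "STCategory",
    "MappingConfig",
    "ToneParams",
    "LeadTone",
    "OrderedLeadSequence",
    "categorize",
    "pitch_offset",
    "semitone_to_frequency",
    "tone_params",
    "order_leads",
]


class STCategory(enum.IntEnum):
    """Five ordered ST states split at the +-theta1 and +-theta2 thresholds."""

    STRONG_SUPPRESSION = 0
    MODERATE_SUPPRESSION = 1
    ISOELECTRIC = 2
    MODERATE_ELEVATION = 3
    STRONG_ELEVATION = 4


MODES = ("continuous", "chromatic", "diatonic", "five_state",
         "five_state_dissonant", "tristate")
CHANNEL_MODES = ("cabrera", "counterclockwise")

#: Harmonic five-state preset (major-chord tones e, g, c', e', g').
FIVE_STATE_HARMONIC_PRESET = (-9, -5, 0, 4, 7)


@dataclass(frozen=True)
class MappingConfig:
    """All sonification hyperparameters of the grouped-lead-scan design.

    Defaults are the evaluated study configuration: five-state mapping with
    semitone offsets (-8, -5, 0, +4, +7) around f0 = 554 Hz, Cabrera
    channel ordering with -aVR, inter-tone interval dt = 120 ms, set
    separation 8 beats, stride 2 beats, base level L0 = -25 dB with
    dBscale = 0.2.
    """

    mode: str = "five_state"
    theta1: float = 0.1
    theta2: float = 0.2
    source_interval: tuple[float, float] = (-0.4, 0.4)
    five_state_offsets: tuple[int, ...] = (-8, -5, 0, 4, 7)
    dissonant_offsets: tuple[int, ...] = (-11, -5, 0, 4, 8)
    tristate_offsets: tuple[int, ...] = (-5, 0, 7)
    diatonic_offsets: tuple[int, ...] = (-10, -8, -7, -5, -3, -1,
                                         0, 2, 4, 5, 7, 9)
    channel_mode: str = "cabrera"
    f0: float = 554.0
    dt_s: float = 0.120
    stride_beats: int = 2
    set_separation_beats: int = 8
    base_level_db: float = -25.0
    db_scale: float = 0.2

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; one of {MODES}")
        if self.channel_mode not in CHANNEL_MODES:
            raise ValueError(
                f"unknown channel_mode {self.channel_mode!r}; "
                f"one of {CHANNEL_MODES}")
        if not 0 < self.theta1 < self.theta2:
            raise ValueError("need 0 < theta1 < theta2")
        lo, hi = self.source_interval
        if not math.isclose(lo, -hi) or hi <= 0:
            raise ValueError("source_interval must be symmetric about 0")
        for name in ("five_state_offsets", "dissonant_offsets",
                     "tristate_offsets", "diatonic_offsets"):
            tab = getattr(self, name)
            if any(a > b for a, b in zip(tab, tab[1:])):
                raise ValueError(f"{name} must be sorted ascending")
        if len(self.five_state_offsets) != 5 or len(self.dissonant_offsets) != 5:
            raise ValueError("five-state offset tables need 5 entries")
        if len(self.tristate_offsets) != 3:
            raise ValueError("tristate_offsets needs 3 entries")
        if len(self.diatonic_offsets) != 12:
            raise ValueError("diatonic_offsets needs 12 entries")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MappingConfig":
        d = dict(d)
        for key in ("source_interval", "five_state_offsets",
                    "dissonant_offsets", "tristate_offsets",
                    "diatonic_offsets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MappingConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def categorize(st: float, theta1: float = 0.1,
               theta2: float = 0.2) -> STCategory:
    """Discretize an ST value (mV) into the five ordered states.

    The isoelectric band is closed ([-theta1, theta1]), the moderate bands
    are half-open outward, and the strong bands lie strictly beyond
    +-theta2.
    """
    if not math.isfinite(st):
        raise ValueError(f"non-finite ST value: {st}")
    if not theta1 < theta2:
        raise ValueError("need theta1 < theta2")
    if st < -theta2:
        return STCategory.STRONG_SUPPRESSION
    if st < -theta1:
        return STCategory.MODERATE_SUPPRESSION
    if st <= theta1:
        return STCategory.ISOELECTRIC
    if st <= theta2:
        return STCategory.MODERATE_ELEVATION
    return STCategory.STRONG_ELEVATION


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def pitch_offset(st: float, cfg: MappingConfig) -> float:
    """Semitone offset from f0 for an ST value under the configured mode."""
    if not math.isfinite(st):
        raise ValueError(f"non-finite ST value: {st}")
    lo, hi = cfg.source_interval
    clamped = min(max(st, lo), hi)

    if cfg.mode == "continuous":
        return (clamped - lo) / (hi - lo) * 14.0 - 7.0
    if cfg.mode == "chromatic":
        return float(_round_half_away((clamped - lo) / (hi - lo) * 14.0 - 7.0))
    if cfg.mode == "diatonic":
        i = _round_half_away((clamped - lo) / (hi - lo) * 11.0)
        return float(cfg.diatonic_offsets[i])
    if cfg.mode == "five_state":
        return float(cfg.five_state_offsets[
            categorize(st, cfg.theta1, cfg.theta2)])
    if cfg.mode == "five_state_dissonant":
        return float(cfg.dissonant_offsets[
            categorize(st, cfg.theta1, cfg.theta2)])
    if cfg.mode == "tristate":
        if st < -cfg.theta1:
            return float(cfg.tristate_offsets[0])
        if st <= cfg.theta1:
            return float(cfg.tristate_offsets[1])
        return float(cfg.tristate_offsets[2])
    raise ValueError(f"unknown mode {cfg.mode!r}")


def semitone_to_frequency(k: float, f0: float = 554.0) -> float:
    """Equal-temperament frequency of a semitone offset: f0 * 2**(k/12)."""
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    return f0 * 2.0 ** (k / 12.0)


@dataclass(frozen=True)
class ToneParams:
    """Per-tone rendering parameters derived from |st|."""

    duration_s: float
    level_boost_db: float
    n_harmonics: int
    envelope_curve: float
    level_db: float  # final: base_level_db + db_scale * level_boost_db


def tone_params(st: float, cfg: MappingConfig) -> ToneParams:
    """Duration/level/timbre stepped over the |st| <= theta1/theta2 bands.

    50 ms / no boost / 2 harmonics / percussive curve (-3) inside the
    isoelectric band; 80 ms / +5 dB / 4 harmonics / sustained curve (+3)
    in the moderate band; 100 ms / +15 dB beyond theta2.  The boost is
    scaled by db_scale onto the base level.
    """
    if not math.isfinite(st):
        raise ValueError(f"non-finite ST value: {st}")
    a = abs(st)
    if a <= cfg.theta1:
        duration, boost = 0.050, 0.0
    elif a <= cfg.theta2:
        duration, boost = 0.080, 5.0
    else:
        duration, boost = 0.100, 15.0
    n_harmonics = 2 if a <= cfg.theta1 else 4
    curve = -3.0 if a <= cfg.theta1 else 3.0
    return ToneParams(
        duration_s=duration,
        level_boost_db=boost,
        n_harmonics=n_harmonics,
        envelope_curve=curve,
        level_db=cfg.base_level_db + cfg.db_scale * boost,
    )


@dataclass(frozen=True)
class LeadTone:
    """One entry of an ordered lead sequence: display label + mV value."""

    label: str
    value: float
    negated: bool = False


@dataclass(frozen=True)
class OrderedLeadSequence:
    """Limb group then precordial group, in playback order."""

    limb_group: tuple[LeadTone, ...]
    precordial_group: tuple[LeadTone, ...]

    def __iter__(self):
        yield from self.limb_group
        yield from self.precordial_group


def order_leads(profile: STProfile,
                channel_mode: str = "cabrera") -> OrderedLeadSequence:
    """Arrange the 12 ST values into the playback sequence.

    In ``cabrera`` mode the limb order is aVL, I, -aVR, II, aVF, III with
    the aVR value sign-flipped (so its displayed elevation matches the
    inverted lead); ``counterclockwise`` plays aVR, III, aVF, II, I, aVL
    with no negation.  The precordial group is always V1..V6.
    """
    if channel_mode == "cabrera":
        limb = tuple(
            LeadTone("-aVR", -profile[k], True) if k == "aVR"
            else LeadTone(k, profile[k])
            for k in CABRERA_LIMB_ORDER
        )
    elif channel_mode == "counterclockwise":
        limb = tuple(LeadTone(k, profile[k])
                     for k in COUNTERCLOCKWISE_LIMB_ORDER)
    else:
        raise ValueError(f"unknown channel_mode {channel_mode!r}; "
                         f"one of {CHANNEL_MODES}")
    precordial = tuple(LeadTone(k, profile[k]) for k in PRECORDIAL_ORDER)
    return OrderedLeadSequence(limb_group=limb, precordial_group=precordial)
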