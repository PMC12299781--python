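"""The 12 standard ECG leads and the orderings used throughout the package.

The standard 12-lead ECG comprises three limb leads (I, II, III), three
augmented limb leads (aVR, aVL, aVF) and six precordial leads (V1-V6).
Sequences over leads are always formed with an explicit ordering; the
orderings defined here are the ones the sonification designs use.
"""

from __future__ import annotations

#: Standard display order: limb, augmented, precordial.
STANDARD_ORDER: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Frontal-plane leads arranged along the Cabrera circle with aVR inverted
#: (displayed as -aVR), progressing from lateral to inferior.
CABRERA_LIMB_ORDER: tuple[str, ...] = ("aVL", "I", "aVR", "II", "aVF", "III")

#: Counterclockwise frontal-plane order, inferior to lateral; aVR un-negated.
COUNTERCLOCKWISE_LIMB_ORDER: tuple[str, ...] = (
    "aVR", "III", "aVF", "II", "I", "aVL",
)

#: Precordial leads, septal via anterior to lateral.
PRECORDIAL_ORDER: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5", "V6")

LEAD_NAMES = frozenset(STANDARD_ORDER)


def validate_lead_names(names) -> None:
    """Raise ``ValueError`` unless *names* is exactly the 12 standard leads."""
    names = set(names)
    if names != LEAD_NAMES:
        missing = sorted(LEAD_NAMES - names)
        extra = sorted(names - LEAD_NAMES)
        parts = []
        if missing:
            parts.append(f"missing leads: {missing}")
        if extra:
            parts.append(f"unknown leads: {extra}")
        raise ValueError("expected exactly the 12 standard ECG leads; "
                         + "; ".join(parts))
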