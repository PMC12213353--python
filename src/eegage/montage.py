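"""Canonical 10-20 montage and scalp-region electrode groupings.

The package works on the classic 19-electrode subset of the international
10-20 system. Recordings are reordered to :data:`CANONICAL_19` before any
referencing or filtering so that channel indices are stable everywhere
downstream (region selection, model input layout, serialization).
"""

from __future__ import annotations

# Fixed channel order; every array with a channel axis follows it.
CANONICAL_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

# Channels that may appear in clinical EDF exports but are not scalp EEG;
# dropped silently during canonicalization (auricular references etc.).
NON_SCALP_LABELS: frozenset[str] = frozenset(
    {"A1", "A2", "M1", "M2", "ECG", "EKG", "EOG", "EMG", "Status"}
)

REGIONS: dict[str, tuple[str, ...]] = {
    "whole": CANONICAL_19,
    "frontal": ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"),
    "central": ("C3", "C4", "Cz"),
    "parietal": ("P3", "P4", "Pz"),
    "occipital": ("O1", "O2"),
    "temporal": ("T3", "T4", "T5", "T6"),
}

REGION_NAMES: tuple[str, ...] = tuple(REGIONS)
#: The five sub-regions (everything except the whole-scalp model).
SUBREGION_NAMES: tuple[str, ...] = tuple(n for n in REGIONS if n != "whole")


def region_channels(region: str) -> tuple[str, ...]:
    """Electrode labels belonging to a scalp region.

    Parameters
    ----------
    region
        One of ``whole, frontal, central, parietal, occipital, temporal``.
    """
    try:
        return REGIONS[region]
    except KeyError:
        raise ValueError(
            f"unknown region {region!r}; expected one of {sorted(REGIONS)}"
        ) from None


def region_indices(region: str, channel_labels: list[str] | tuple[str, ...]) -> list[int]:
    """Indices of a region's electrodes within ``channel_labels``."""
    labels = list(channel_labels)
    idx = []
    for name in region_channels(region):
        if name not in labels:
            raise ValueError(f"channel {name!r} (region {region!r}) missing from recording")
        idx.append(labels.index(name))
    return idx


def _normalize_label(label: str) -> str:
    """Map vendor spellings (``EEG Fp1-Ref``, ``FP1``, ``T7``) onto canonical names."""
    s = label.strip()
    if s.upper().startswith("EEG "):
        s = s[4:]
    s = s.split("-")[0].strip()
    aliases = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}
    lut = {c.upper(): c for c in CANONICAL_19}
    up = s.upper()
    up = {a.upper(): b for a, b in aliases.items()}.get(up, up)
    return lut.get(up, s)
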