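"""Standard 10-20 scalp montage: labels, schematic positions, adjacency, hemisphere sets.

Positions are schematic 2-D head coordinates (nose up, unit circle head outline),
sufficient for nearest-neighbour interpolation and topographic maps; they are not
digitized electrode locations.
"""

from __future__ import annotations

# Canonical 19-channel 10-20 set, classic T3/T4/T5/T6 naming.
LABELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

MIDLINE: frozenset[str] = frozenset({"Fz", "Cz", "Pz"})

LEFT_LATERAL: tuple[str, ...] = ("Fp1", "F3", "F7", "C3", "T3", "P3", "T5", "O1")
RIGHT_LATERAL: tuple[str, ...] = ("Fp2", "F4", "F8", "C4", "T4", "P4", "T6", "O2")

# Schematic coordinates: x positive right, y positive anterior.
POSITIONS_1020: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.52), "F8": (0.81, 0.59),
    "T3": (-1.00, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.00, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.40, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

# Schematic grid adjacency used for nearest-neighbour bad-channel interpolation.
ADJACENCY_1020: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F3", "F7", "Fz"),
    "Fp2": ("Fp1", "F4", "F8", "Fz"),
    "F7": ("Fp1", "F3", "T3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("Fp1", "Fp2", "F3", "F4", "Cz"),
    "F4": ("Fp2", "F8", "Fz", "C4"),
    "F8": ("Fp2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "T4", "Cz", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4", "O1", "O2"),
    "P4": ("C4", "T6", "Pz", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "Pz", "O2"),
    "O2": ("T6", "P4", "Pz", "O1"),
}

POSTERIOR: frozenset[str] = frozenset({"O1", "O2", "P3", "P4", "T5", "T6"})

# Ocular (blink) projection weights: frontal channels dominate.
OCULAR_WEIGHTS: dict[str, float] = {
    **{lab: 0.1 for lab in LABELS_1020},
    "Fp1": 1.0, "Fp2": 1.0,
    "F3": 0.5, "F4": 0.5, "F7": 0.5, "F8": 0.5,
}

# Synonym map for EDF label normalization ("EEG Fp1-REF" etc. handled separately).
MODERN_TO_CLASSIC: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def normalize_label(raw: str) -> str:
    """Map an EDF channel label like ``"EEG Fp1-REF"`` or ``"T7"`` to its 10-20 name.

    Returns the cleaned label; unknown channels come back stripped but unmapped.
    """
    s = raw.strip()
    if s.upper().startswith("EEG "):
        s = s[4:]
    s = s.split("-")[0].strip()
    # case-insensitive match against the canonical set
    lut = {lab.lower(): lab for lab in LABELS_1020}
    lut.update({k.lower(): v for k, v in MODERN_TO_CLASSIC.items()})
    return lut.get(s.lower(), s)


def hemisphere_sets(affected_side: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Return (affected, unaffected) lateral channel sets for a lesion side."""
    if affected_side == "L":
        return LEFT_LATERAL, RIGHT_LATERAL
    if affected_side == "R":
        return RIGHT_LATERAL, LEFT_LATERAL
    raise ValueError(f"affected_side must be 'L' or 'R', got {affected_side!r}")
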