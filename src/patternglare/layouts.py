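"""Stylized BioSemi-style electrode layouts on the unit head disc.

Coordinates are 2-D positions on a unit disc viewed from above (nose up):
x increases to the participant's right, y towards the nose.  Electrode
names follow the BioSemi A/B/C/D bank convention, with the A bank over
posterior-midline sites, B over the right posterior quadrant, C over the
right/midline frontal region and D over the left frontal quadrant.  The
geometry is a stylized approximation adequate for simulation and for
distance-based adjacency; it is not a digitised cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Layout", "biosemi32", "subset_layout", "DEFAULT_16", "DEFAULT_4"]

# name: (x, y) on the unit disc
_BIOSEMI32 = {
    # A bank: posterior midline / left posterior
    "A1": (0.00, 0.00),
    "A3": (-0.30, -0.15),
    "A5": (-0.55, -0.35),
    "A7": (-0.25, -0.40),
    "A15": (-0.45, -0.60),
    "A19": (0.00, -0.40),
    "A21": (-0.20, -0.65),
    "A23": (-0.15, -0.85),
    "A25": (0.00, -0.72),
    "A29": (0.15, -0.88),
    "A31": (0.18, -0.70),
    # B bank: right posterior
    "B2": (0.30, -0.15),
    "B5": (0.38, -0.58),
    "B8": (0.15, -0.55),
    "B11": (0.55, -0.40),
    "B16": (0.45, -0.70),
    "B22": (0.40, 0.00),
    "B26": (0.65, -0.15),
    # C bank: right / midline frontal
    "C3": (0.20, 0.35),
    "C7": (0.45, 0.30),
    "C13": (0.25, 0.60),
    "C17": (0.00, 0.55),
    "C21": (0.00, 0.80),
    "C24": (0.45, 0.62),
    "C30": (0.15, 0.88),
    # D bank: left frontal
    "D4": (-0.20, 0.35),
    "D8": (-0.45, 0.30),
    "D13": (-0.25, 0.60),
    "D19": (-0.40, 0.00),
    "D23": (-0.15, 0.80),
    "D28": (-0.60, 0.15),
    "D31": (-0.55, 0.45),
}

# posterior-weighted 16-channel subset used for fast simulated studies
DEFAULT_16 = [
    "A1", "A7", "A19", "A21", "A25", "A29", "A31",
    "B2", "B5", "B8", "B11", "B16",
    "C3", "C17", "D4", "D19",
]

DEFAULT_4 = ["A25", "B16", "C13", "D13"]


@dataclass(frozen=True)
class Layout:
    """Named 2-D electrode positions."""

    names: tuple[str, ...]
    pos: np.ndarray = field(repr=False)  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(self.names) != self.pos.shape[0]:
            raise ValueError("names and positions disagree in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate electrode names")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix in layout units."""
        d = self.pos[:, None, :] - self.pos[None, :, :]
        return np.sqrt((d**2).sum(-1))


def biosemi32() -> Layout:
    """The full 32-channel stylized layout."""
    names = tuple(_BIOSEMI32)
    pos = np.array([_BIOSEMI32[n] for n in names], dtype=float)
    return Layout(names, pos)


def subset_layout(names: list[str] | tuple[str, ...]) -> Layout:
    """Restrict the 32-channel layout to the given electrode names."""
    missing = [n for n in names if n not in _BIOSEMI32]
    if missing:
        raise KeyError(f"unknown electrodes: {missing}")
    pos = np.array([_BIOSEMI32[n] for n in names], dtype=float)
    return Layout(tuple(names), pos)
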