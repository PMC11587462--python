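"""In-memory data containers shared across the pipeline.

``EpochsVolume`` holds single-onset epochs (epoch x channel x time, in
microvolts) together with the time axis and channel geometry.  Epoch
rows are aligned one-to-one with rows of the trial table (see the
``epoch`` column produced by the simulator).

``BinnedData`` is the dependent-variable object the mass-univariate
analysis consumes: participant x bin x condition x channel x time, where
the binning scheme is one of the four used in the study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["EpochsVolume", "BinnedData", "SCHEMES", "scheme_bins"]


@dataclass
class EpochsVolume:
    """Epoched EEG in microvolts with axis metadata."""

    data: np.ndarray               # (n_epochs, n_channels, n_times)
    sfreq: float
    tmin: float
    ch_names: tuple[str, ...]
    ch_pos: np.ndarray             # (n_channels, 2) layout positions
    average_referenced: bool = False
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be epoch x channel x time")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match ch_names")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.sfreq

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        t = self.times
        lo, hi = window
        return (t >= lo - 1e-9) & (t <= hi + 1e-9)

    def with_data(self, data: np.ndarray, **kw) -> "EpochsVolume":
        return replace(self, data=data, **kw)


# Each scheme maps to an ordered list of bins (label, partition-or-None,
# onset set).  Onset 1 (surprise) and onset 9 (rare, noisy) are excluded
# everywhere; onset 8 contributes to the 2-8 average and the partition
# bins but to no onset-pair bin.
_ONSETS_2_8 = frozenset(range(2, 9))
_PAIRS = [("pair_23", frozenset({2, 3})),
          ("pair_45", frozenset({4, 5})),
          ("pair_67", frozenset({6, 7}))]

SCHEMES: dict[str, list[tuple[str, Optional[int], frozenset]]] = {
    "onsets_2_8": [("onsets_2_8", None, _ONSETS_2_8)],
    "partitions": [(f"partition{p}", p, _ONSETS_2_8) for p in (1, 2, 3)],
    "onset_pairs": [(lbl, None, s) for lbl, s in _PAIRS],
    "partition_by_onset_pair": [
        (f"P{p}:{lbl}", p, s) for p in (1, 2, 3) for lbl, s in _PAIRS
    ],
}


def scheme_bins(scheme: str):
    if scheme not in SCHEMES:
        raise KeyError(f"unknown binning scheme: {scheme!r}")
    return SCHEMES[scheme]


@dataclass
class BinnedData:
    """Binned dependent variables: participant x bin x condition x channel x time."""

    scheme: str
    values: np.ndarray             # (P, B, K, C, T), NaN where a cell is missing
    counts: np.ndarray             # (P, B, K) contributing usable epochs
    participants: tuple
    bin_labels: tuple[str, ...]
    conditions: tuple[str, ...]
    sfreq: float
    times: np.ndarray = field(repr=False)
    ch_names: tuple[str, ...] = ()
    ch_pos: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        P, B, K = len(self.participants), len(self.bin_labels), len(self.conditions)
        if self.values.shape[:3] != (P, B, K):
            raise ValueError("values shape does not match labels")
        if self.counts.shape != (P, B, K):
            raise ValueError("counts shape does not match labels")

    @property
    def n_bins(self) -> int:
        return len(self.bin_labels)

    def condition(self, name: str) -> np.ndarray:
        return self.values[:, :, self.conditions.index(name)]

    def complete_participants(self) -> np.ndarray:
        """Boolean mask of participants with no missing required cell."""
        return (self.counts > 0).all(axis=(1, 2))

    def drop_incomplete(self) -> "BinnedData":
        """Drop participants with any empty cell (per-scheme policy)."""
        keep = self.complete_participants()
        return replace(
            self,
            values=self.values[keep],
            counts=self.counts[keep],
            participants=tuple(np.asarray(self.participants)[keep].tolist()),
        )

    def restrict_window(self, window: tuple[float, float]) -> "BinnedData":
        lo, hi = window
        mask = (self.times >= lo - 1e-9) & (self.times <= hi + 1e-9)
        if not mask.any():
            raise ValueError(f"analysis window {window} is empty for this time axis")
        return replace(self, values=self.values[..., mask], times=self.times[mask])
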