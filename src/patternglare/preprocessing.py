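"""Preprocessing: filtering, referencing, baseline, rejection, binning, PGI.

All operations are pure: they return new :class:`EpochsVolume` /
:class:`BinnedData` objects and never mutate their inputs.  Stages that
affect which epochs are usable also return updated trial tables so the
epoch/trial alignment is preserved.

The binning stage turns epochs into the four dependent-variable layouts
of the analysis: the collapsed average of onsets 2-8, the three
partitions (experimental blocks), the three onset-pairs {2,3}/{4,5}/
{6,7}, and the 3 x 3 partition-by-onset-pair grid.  Onset 1 (surprise)
and onset 9 (rare) never contribute.  The Pattern Glare Index

    PGI = medium - (thick + thin) / 2

is computed elementwise per participant x bin over channel x time; it
is zero whenever the medium response sits at the control midpoint, the
expected outcome for purely visual (spatial-frequency) effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin

from .config import STIMULI
from .containers import BinnedData, EpochsVolume, scheme_bins

__all__ = [
    "bandpass_filter", "decimate", "rereference_average", "baseline_correct",
    "reject_threshold", "include_participants", "bin_average", "compute_pgi",
    "RejectionResult",
]

log = logging.getLogger(__name__)

# windowed-FIR length heuristic: ~3.3 cycles of the transition band
_TRANS_FACTOR = 3.3
_DEFAULT_TRANS_HIGH = 7.5  # Hz


def design_fir(sfreq: float, low: float | None, high: float | None,
               trans_high: float = _DEFAULT_TRANS_HIGH) -> np.ndarray:
    """Hann-windowed linear-phase FIR taps for the requested band.

    Band-pass and high-pass designs are forced to an exact null at DC by
    zero-summing the taps, so a constant offset across the whole record
    is fully removed regardless of filter length.
    """
    nyq = sfreq / 2.0
    if high is not None and not (0 < high < nyq):
        raise ValueError(f"high edge {high} Hz inconsistent with sfreq {sfreq} Hz")
    if low is not None and high is not None and not (0 < low < high):
        raise ValueError("need 0 < low < high")
    numtaps = int(np.ceil(_TRANS_FACTOR * sfreq / trans_high))
    numtaps += 1 - numtaps % 2  # odd length -> symmetric, zero-phase applicable
    if low is None and high is None:
        raise ValueError("at least one band edge is required")
    if low is None:
        return firwin(numtaps, high, window="hann", fs=sfreq)
    if high is None:
        h = firwin(numtaps, low, window="hann", pass_zero=False, fs=sfreq)
    else:
        h = firwin(numtaps, [low, high], window="hann", pass_zero=False, fs=sfreq)
    # force an exact DC null by removing a Hann-shaped component: its
    # spectrum is concentrated at 0 Hz, so the passband is untouched
    # (a flat correction would spray Dirichlet-kernel ripple across it)
    w = np.hanning(numtaps)
    return h - (h.sum() / w.sum()) * w


def bandpass_filter(epochs: EpochsVolume, low: float | None = 0.1,
                    high: float | None = 30.0) -> EpochsVolume:
    """Zero-phase windowed-FIR filter applied per epoch and channel.

    Epoch edges are reflection-padded by half the filter length before
    the (symmetric, linear-phase) kernel is applied, so no group delay
    or edge truncation is introduced.
    """
    h = design_fir(epochs.sfreq, low, high)
    pad = len(h) // 2
    if pad >= epochs.n_times:
        raise ValueError("epoch too short for the requested filter length")
    padded = np.pad(epochs.data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    out = fftconvolve(padded, h[None, None, :], mode="same", axes=2)
    out = out[..., pad:-pad]
    return epochs.with_data(out)


def decimate(epochs: EpochsVolume, factor: int) -> EpochsVolume:
    """Downsample by an integer factor (anti-alias filtering is the
    caller's responsibility; the 30 Hz low-pass suffices when run first)."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return epochs.with_data(epochs.data.copy())
    return epochs.with_data(epochs.data[..., ::factor].copy(),
                            sfreq=epochs.sfreq / factor)


def rereference_average(epochs: EpochsVolume) -> EpochsVolume:
    """Re-reference to the instantaneous average of all electrodes."""
    if epochs.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    out = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.with_data(out, average_referenced=True)


def baseline_correct(epochs: EpochsVolume,
                     window: tuple[float, float] = (-0.2, 0.0)) -> EpochsVolume:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    mask = epochs.time_mask(window)
    if not mask.any():
        raise ValueError(f"baseline window {window} outside the epoch")
    out = epochs.data - epochs.data[..., mask].mean(axis=2, keepdims=True)
    return epochs.with_data(out, baseline_corrected=True)


@dataclass
class RejectionResult:
    epochs: EpochsVolume       # surviving epochs only
    trials: pd.DataFrame       # full table with updated ``usable`` flags
    log: pd.DataFrame          # one row per rejected epoch


def reject_threshold(epochs: EpochsVolume, limit: float,
                     trials: pd.DataFrame) -> RejectionResult:
    """Drop every epoch with any |value| above ``limit`` microvolts."""
    if limit <= 0:
        raise ValueError("rejection limit must be positive")
    absmax = np.abs(epochs.data).max(axis=2)          # (E, C)
    bad = (absmax > limit).any(axis=1)
    worst_ch = absmax.argmax(axis=1)
    flat = epochs.data[np.arange(epochs.n_epochs), worst_ch]
    extremum = flat[np.arange(epochs.n_epochs), np.abs(flat).argmax(axis=1)]
    entries = []
    for e in np.flatnonzero(bad):
        row = trials.iloc[e]
        entries.append((row["participant"], row["trial"], row["onset"],
                        epochs.ch_names[worst_ch[e]], float(extremum[e])))
    log_df = pd.DataFrame(entries, columns=["participant", "trial", "onset",
                                            "channel", "extremum"])
    trials_out = trials.copy()
    trials_out.loc[trials_out.index[bad], "usable"] = False
    kept = epochs.with_data(epochs.data[~bad])
    if bad.any():
        log.info("rejected %d/%d epochs at +-%g uV", int(bad.sum()),
                 epochs.n_epochs, limit)
    return RejectionResult(kept, trials_out, log_df)


def include_participants(trials: pd.DataFrame, min_fraction: float = 0.2,
                         conditions: tuple[str, ...] = STIMULI) -> list:
    """Participants with >= ``min_fraction`` usable epochs in every condition.

    The boundary is inclusive: exactly 20% usable keeps a participant.
    """
    if trials.empty:
        raise ValueError("empty trial table")
    kept = []
    for p, sub in trials.groupby("participant", sort=True):
        ok = True
        for cond in conditions:
            cond_rows = sub[sub["stimulus"] == cond]
            total = len(cond_rows)
            if total == 0 or cond_rows["usable"].sum() / total < min_fraction - 1e-12:
                ok = False
                break
        if ok:
            kept.append(p)
        else:
            log.info("participant %s excluded by the %g%% usable-trial rule",
                     p, 100 * min_fraction)
    return kept


def bin_average(epochs: EpochsVolume, trials: pd.DataFrame, scheme: str,
                participants: list | None = None) -> BinnedData:
    """Average usable epochs into the cells of a binning scheme.

    Epochs are weighted equally within a cell.  Cells with zero usable
    epochs are NaN with a zero count.
    """
    bins = scheme_bins(scheme)
    usable = trials[trials["usable"]]
    if participants is None:
        participants = sorted(usable["participant"].unique())
    missing = set(participants) - set(trials["participant"].unique())
    if missing:
        raise KeyError(f"participants absent from the trial table: {sorted(missing)}")
    # surviving-epoch row positions: usable rows of the table map 1:1, in
    # order, onto the rows of the post-rejection volume
    if len(usable) != epochs.n_epochs:
        raise ValueError("epochs and usable trial rows are out of alignment")
    row_of = pd.Series(np.arange(len(usable)), index=usable.index)

    P, B, K = len(participants), len(bins), len(STIMULI)
    values = np.full((P, B, K, epochs.n_channels, epochs.n_times), np.nan)
    counts = np.zeros((P, B, K), dtype=int)
    pidx = {p: i for i, p in enumerate(participants)}

    for (p, stim), sub in usable.groupby(["participant", "stimulus"], sort=False):
        if p not in pidx:
            continue
        k = STIMULI.index(stim)
        onsets = sub["onset"].to_numpy()
        parts = sub["partition"].to_numpy()
        rows = row_of[sub.index].to_numpy()
        for b, (_, partition, onset_set) in enumerate(bins):
            sel = np.isin(onsets, list(onset_set))
            if partition is not None:
                sel &= parts == partition
            if sel.any():
                values[pidx[p], b, k] = epochs.data[rows[sel]].mean(axis=0)
                counts[pidx[p], b, k] = int(sel.sum())

    return BinnedData(
        scheme=scheme, values=values, counts=counts,
        participants=tuple(participants),
        bin_labels=tuple(lbl for lbl, _, _ in bins),
        conditions=STIMULI, sfreq=epochs.sfreq, times=epochs.times,
        ch_names=epochs.ch_names, ch_pos=epochs.ch_pos,
    )


def compute_pgi(binned: BinnedData) -> BinnedData:
    """Pattern Glare Index: medium minus the mean of thick and thin."""
    for cond in STIMULI:
        if cond not in binned.conditions:
            raise ValueError(f"condition {cond!r} missing from binned data")
    med = binned.condition("medium")
    thick = binned.condition("thick")
    thin = binned.condition("thin")
    pgi = med - 0.5 * (thick + thin)
    counts = binned.counts.min(axis=2, keepdims=True)
    return replace(binned, values=pgi[:, :, None], counts=counts,
                   conditions=("PGI",))
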