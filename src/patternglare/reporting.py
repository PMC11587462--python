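"""Reporting: grand averages, bootstrap bands, median splits, tables, exports.

Grand averages are across-participant means of the per-participant
series; 95% confidence bands come from a percentile bootstrap that
resamples whole participants with replacement, with one resample per
iteration driving every condition (this preserves the cross-condition
correlation the PGI bands depend on).  For factor analyses the
participants are split at the median factor score into high/low groups
for visualisation; ties at the median go to the low group, a fixed rule
chosen for determinism.

Delimited text products are the canonical outputs; figures are a thin
rendering layer on top of them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BinnedData
from .mua import MuaResult

__all__ = ["median_split", "bootstrap_ci", "grand_average", "cluster_table",
           "export_products", "FLOAT_FORMAT"]

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


def median_split(scores: pd.Series) -> tuple[list, list, float]:
    """Split participants at the median score: (low, high, median).

    ``high`` holds scores strictly above the median; everyone else —
    including participants exactly at the median — goes to ``low``.
    """
    if len(scores) < 2:
        raise ValueError("median split needs at least 2 participants")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; median split undefined")
    med = float(scores.median())
    high = scores.index[scores > med].tolist()
    low = scores.index[scores <= med].tolist()
    return low, high, med


def bootstrap_ci(series: np.ndarray, n_boot: int = 5_000, level: float = 0.95,
                 seed=0) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap bands for the across-participant mean.

    ``series`` has participants on axis 0; any trailing axes (condition,
    channel, time) ride along, resampled jointly.  Returns (lower,
    upper) with the participant axis collapsed.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    if n < 2:
        raise ValueError("bootstrap needs at least 2 participants")
    if n_boot < 100:
        import warnings
        warnings.warn(f"n_boot={n_boot} is small for percentile intervals",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    surrogate = series[idx].mean(axis=1)            # (n_boot, ...)
    lo_q = (1.0 - level) / 2.0
    lower = np.quantile(surrogate, lo_q, axis=0)
    upper = np.quantile(surrogate, 1.0 - lo_q, axis=0)
    return lower, upper


def grand_average(series: np.ndarray) -> np.ndarray:
    """Across-participant mean (participants on axis 0)."""
    return np.asarray(series, dtype=float).mean(axis=0)


def cluster_table(results: dict[str, MuaResult],
                  p_cutoff: float = 0.1) -> pd.DataFrame:
    """One row per cluster with p below the reporting cutoff.

    Rows are sorted by p ascending within each (scheme, regressor)
    analysis; columns follow the effect-table convention (p, peak
    electrode, peak time, r, both d conventions, extent).
    """
    rows = []
    for name, res in results.items():
        for c in res.clusters:
            if c.p_value is None or c.p_value >= p_cutoff:
                continue
            rows.append({
                "scheme": res.scheme,
                "regressor": res.regressor_name,
                "tail": c.tail,
                "p_value": c.p_value,
                "electrode": c.peak_channel,
                "peak_time_s": c.peak_time,
                "r_effect": c.r_effect,
                "d_one_sample": c.d_one_sample,
                "d_regression": c.d_regression,
                "temporal_extent_s": c.temporal_extent,
                "n_members": c.n_members,
                "mass": c.mass,
                "significant": c.p_value <= res.alpha,
            })
    cols = ["scheme", "regressor", "tail", "p_value", "electrode", "peak_time_s",
            "r_effect", "d_one_sample", "d_regression", "temporal_extent_s",
            "n_members", "mass", "significant"]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values(["scheme", "regressor", "p_value"],
                                  kind="mergesort").reset_index(drop=True)
    return table


def _write(df: pd.DataFrame, path: Path) -> None:
    try:
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    except OSError as err:
        raise OSError(f"failed writing report product {path}: {err}") from err


def _grand_average_frame(binned: BinnedData, ch: int, groups: dict[str, list],
                         n_boot: int, level: float, seed) -> pd.DataFrame:
    """Long-format grand averages with CI bands at one electrode."""
    rows = []
    part = np.asarray(binned.participants)
    for g, (gname, members) in enumerate(groups.items()):
        sel = np.isin(part, members)
        if not sel.any():
            continue
        sub = binned.values[sel][:, :, :, ch, :]     # (p, B, K, T)
        mean = sub.mean(axis=0)
        lower, upper = bootstrap_ci(sub, n_boot=n_boot, level=level,
                                    seed=[seed, g])
        for b, blab in enumerate(binned.bin_labels):
            for k, cond in enumerate(binned.conditions):
                for ti, tval in enumerate(binned.times):
                    rows.append((gname, blab, cond, tval, mean[b, k, ti],
                                 lower[b, k, ti], upper[b, k, ti]))
    return pd.DataFrame(rows, columns=["group", "bin", "condition", "time_s",
                                       "mean_uV", "ci_lower_uV", "ci_upper_uV"])


def export_products(outdir, results: dict[str, MuaResult],
                    binned_by_scheme: dict[str, BinnedData],
                    groups_by_regressor: dict[str, dict[str, list]] | None = None,
                    *, n_boot: int = 5_000, ci_level: float = 0.95, seed=0,
                    p_cutoff: float = 0.1, figures: bool = True) -> list[Path]:
    """Write t-map grids, cluster masks, grand averages and the cluster table.

    ``binned_by_scheme`` supplies the per-condition (thin/medium/thick +
    PGI) data used for the grand-average panels; ``groups_by_regressor``
    optionally maps a regressor name to named participant groups (e.g. a
    median split).  Returns the list of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    table = cluster_table(results, p_cutoff=p_cutoff)
    path = outdir / "cluster_table.tsv"
    _write(table, path)
    written.append(path)

    for name, res in results.items():
        sm = res.stat_map
        tmap = pd.DataFrame(sm.t, index=pd.Index(sm.ch_names, name="channel"),
                            columns=[f"{t:.6f}" for t in sm.times])
        path = outdir / f"tmap_{name}.tsv"
        tmap.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
        written.append(path)

        mask = np.zeros_like(sm.t, dtype=int)
        for rank, c in enumerate(res.significant(), start=1):
            mask[c.channels, c.time_indices] = rank * c.tail
        mpath = outdir / f"mask_{name}.tsv"
        pd.DataFrame(mask, index=pd.Index(sm.ch_names, name="channel"),
                     columns=[f"{t:.6f}" for t in sm.times]).to_csv(mpath, sep="\t")
        written.append(mpath)

        # grand averages at the peak electrode of the best cluster
        if not res.clusters:
            continue
        best = res.clusters[0]
        if best.p_value is None or best.p_value >= p_cutoff:
            continue
        scheme_data = binned_by_scheme.get(res.scheme)
        if scheme_data is None:
            continue
        ch = scheme_data.ch_names.index(best.peak_channel)
        groups = {"all": list(scheme_data.participants)}
        if groups_by_regressor and name in groups_by_regressor:
            groups = groups_by_regressor[name]
        ga = _grand_average_frame(scheme_data, ch, groups, n_boot, ci_level, seed)
        gpath = outdir / f"grand_{name}_{best.peak_channel}.tsv"
        _write(ga, gpath)
        written.append(gpath)
        if figures:
            written.append(_render_grand_figure(ga, outdir / f"grand_{name}.png",
                                                best.peak_channel))
        if figures:
            written.append(_render_tmap_figure(res, outdir / f"tmap_{name}.png"))
    log.info("wrote %d report products to %s", len(written), outdir)
    return written


def _render_tmap_figure(res: MuaResult, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sm = res.stat_map
    fig, ax = plt.subplots(figsize=(8, 4))
    vmax = np.abs(sm.t).max() or 1.0
    im = ax.imshow(sm.t, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   extent=[sm.times[0], sm.times[-1], sm.t.shape[0], 0])
    for c in res.significant():
        ax.plot(sm.times[c.time_indices], c.channels + 0.5, "k.", ms=2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("channel index")
    ax.set_title(f"{res.scheme}: {res.regressor_name} (t map)")
    fig.colorbar(im, ax=ax, label="t")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def _render_grand_figure(ga: pd.DataFrame, path: Path, electrode: str) -> Path:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = ga["group"].unique()
    bins = ga["bin"].unique()
    fig, axes = plt.subplots(len(bins), len(groups),
                             figsize=(4.5 * len(groups), 2.2 * len(bins)),
                             squeeze=False, sharex=True)
    for bi, blab in enumerate(bins):
        for gi, gname in enumerate(groups):
            ax = axes[bi][gi]
            sub = ga[(ga["group"] == gname) & (ga["bin"] == blab)]
            for cond, cdat in sub.groupby("condition"):
                ax.plot(cdat["time_s"], cdat["mean_uV"], label=cond, lw=1)
                ax.fill_between(cdat["time_s"], cdat["ci_lower_uV"],
                                cdat["ci_upper_uV"], alpha=0.2)
            ax.axhline(0, color="k", lw=0.5)
            ax.set_title(f"{gname} / {blab} @ {electrode}", fontsize=8)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
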