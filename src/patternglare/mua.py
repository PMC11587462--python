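"""Mass-univariate regression with cluster-based permutation inference.

Per channel x time sample, the participant(-by-bin) Pattern Glare Index
values are regressed on a single design regressor (ordinary least
squares; the all-ones intercept regressor reduces to a one-sample t test
of the mean against zero).  Samples whose t value exceeds the Student-t
quantile at the cluster-forming tail probability are grouped into
connected components under channel adjacency (distance rule on the
electrode layout) at the same timepoint plus temporal succession at the
same channel.  Each cluster's mass is the sum of its member t values
("maxsum" statistic).  Family-wise error is controlled per tail by the
Monte-Carlo permutation distribution of the maximum cluster mass:
sign-flips of whole participants for the intercept, whole-participant
shuffles of the regressor (bins travel with their participant, since
factor scores are between-participant properties) for covariates.
P-values use the (b + 1) / (m + 1) estimator and are never exactly zero.

For sign-flip designs with few participants the engine enumerates all
2^n distinct assignments whenever that is no more than the requested
permutation count, making the Monte-Carlo p exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .containers import BinnedData
from .layouts import Layout
from .regressors import DesignRegressor

__all__ = [
    "AdjacencyGraph", "StatMap", "ClusterResult", "MuaResult",
    "build_adjacency", "samplewise_stat", "form_clusters",
    "permutation_null", "cluster_pvalues", "effect_sizes",
    "select_peak_electrode", "run_mua",
]

log = logging.getLogger(__name__)

T_CAP = 1e6          # cap for degenerate zero-residual fits
_EXHAUSTIVE_MAX = 22  # enumerate sign flips only up to 2^22 assignments


@dataclass
class AdjacencyGraph:
    """Channel neighbourhood structure from a layout distance rule."""

    ch_names: tuple[str, ...]
    pairs: np.ndarray            # (n_edges, 2) channel index pairs, i < j
    distance_threshold: float

    @property
    def mean_degree(self) -> float:
        n = len(self.ch_names)
        return 2.0 * len(self.pairs) / n if n else 0.0

    def neighbor_matrix(self) -> np.ndarray:
        n = len(self.ch_names)
        m = np.zeros((n, n), dtype=bool)
        if len(self.pairs):
            m[self.pairs[:, 0], self.pairs[:, 1]] = True
            m[self.pairs[:, 1], self.pairs[:, 0]] = True
        return m


def build_adjacency(layout: Layout, distance_threshold: float) -> AdjacencyGraph:
    """Edge iff Euclidean layout distance <= threshold (no self loops)."""
    if len(layout) < 2:
        raise ValueError("adjacency needs at least 2 channels")
    d = layout.distances()
    iu, ju = np.triu_indices(len(layout), k=1)
    keep = d[iu, ju] <= distance_threshold
    pairs = np.stack([iu[keep], ju[keep]], axis=1).astype(np.int32)
    graph = AdjacencyGraph(layout.names, pairs, distance_threshold)
    if len(pairs) == 0:
        warnings.warn("adjacency threshold yields an edgeless graph", stacklevel=2)
    log.debug("adjacency: %d edges, mean degree %.2f", len(pairs), graph.mean_degree)
    return graph


def spatiotemporal_edges(adjacency: AdjacencyGraph, n_times: int) -> np.ndarray:
    """Undirected edges over flattened (channel, time) nodes, node = c*T + t."""
    T = n_times
    parts = []
    if len(adjacency.pairs):
        t = np.arange(T)
        a = (adjacency.pairs[:, 0, None] * T + t).ravel()
        b = (adjacency.pairs[:, 1, None] * T + t).ravel()
        parts.append(np.stack([a, b], axis=1))
    c = np.arange(len(adjacency.ch_names))
    a = (c[:, None] * T + np.arange(T - 1)).ravel()
    parts.append(np.stack([a, a + 1], axis=1))
    return np.concatenate(parts).astype(np.int32)


@dataclass
class StatMap:
    """Per-sample t values for one regressor."""

    t: np.ndarray                   # (n_channels, n_times)
    df: int
    n_obs: int
    times: np.ndarray
    ch_names: tuple[str, ...]
    regressor_name: str
    capped: int = 0                 # samples hitting the degenerate-fit cap


def _flatten_pgi(binned: BinnedData) -> np.ndarray:
    """(P, B, 1, C, T) -> rows (B*P, C*T), bin-major row order."""
    if binned.conditions != ("PGI",):
        raise ValueError("mass-univariate stage expects PGI data")
    v = binned.values[:, :, 0]                       # (P, B, C, T)
    if np.isnan(v).any():
        raise ValueError("PGI volume contains missing cells; call "
                         "drop_incomplete() first")
    P, B, C, T = v.shape
    return np.transpose(v, (1, 0, 2, 3)).reshape(B * P, C * T)


def _check_alignment(binned: BinnedData, regressor: DesignRegressor) -> None:
    if tuple(binned.participants) != tuple(regressor.participants):
        raise ValueError("participant order mismatch between data and regressor")
    if tuple(binned.bin_labels) != tuple(regressor.bin_labels):
        raise ValueError("bin-label mismatch between data and regressor")


def _one_sample_t(Y: np.ndarray) -> tuple[np.ndarray, int]:
    n = Y.shape[0]
    mean = Y.mean(axis=0)
    var = Y.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = np.sign(mean[~np.isfinite(t)]) * T_CAP
    capped = int((np.abs(t) >= T_CAP).sum())
    return np.clip(t, -T_CAP, T_CAP), capped


def _slope_t(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    n = x.size
    xc = x - x.mean()
    sx = np.linalg.norm(xc)
    if sx == 0:
        raise ValueError("regressor is constant; use the intercept analysis")
    Yc = Y - Y.mean(axis=0)
    sy = np.linalg.norm(Yc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ Yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0                       # flat data -> zero slope
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    capped = int((np.abs(t) >= T_CAP).sum())
    return np.clip(t, -T_CAP, T_CAP), capped


def samplewise_stat(binned: BinnedData, regressor: DesignRegressor) -> StatMap:
    """OLS t map of the PGI on [1, regressor] per channel x time sample."""
    _check_alignment(binned, regressor)
    Y = _flatten_pgi(binned)
    n = Y.shape[0]
    if regressor.kind == "intercept":
        if n < 2:
            raise ValueError("need at least 2 observations")
        t, capped = _one_sample_t(Y)
        df = n - 1
    else:
        if n < 3:
            raise ValueError("need at least 3 observations for a slope fit")
        t, capped = _slope_t(regressor.values, Y)
        df = n - 2
    C, T = len(binned.ch_names), binned.times.size
    return StatMap(t.reshape(C, T), df, n, binned.times, binned.ch_names,
                   regressor.name, capped)


def _components(mask: np.ndarray, tflat: np.ndarray, edges: np.ndarray):
    """Connected components of the suprathreshold mask; yields (indices, labels)."""
    idx = np.flatnonzero(mask)
    k = idx.size
    if k == 0:
        return idx, np.empty(0, dtype=int)
    em = mask[edges[:, 0]] & mask[edges[:, 1]]
    sub = edges[em]
    remap = np.full(mask.size, -1, dtype=np.int64)
    remap[idx] = np.arange(k)
    g = coo_matrix((np.ones(len(sub), dtype=np.int8),
                    (remap[sub[:, 0]], remap[sub[:, 1]])), shape=(k, k))
    _, labels = connected_components(g, directed=False)
    return idx, labels


def _max_mass(tflat: np.ndarray, thresh: float, tail: int,
              edges: np.ndarray) -> float:
    mask = tflat > thresh if tail > 0 else tflat < -thresh
    idx, labels = _components(mask, tflat, edges)
    if idx.size == 0:
        return 0.0
    masses = np.bincount(labels, weights=tflat[idx])
    return float(np.abs(masses).max())


@dataclass
class ClusterResult:
    """One connected suprathreshold channel x time region."""

    tail: int                       # +1 or -1
    channels: np.ndarray            # member channel indices
    time_indices: np.ndarray        # member time indices (into the window axis)
    mass: float                     # sum of member t values
    p_value: Optional[float] = None
    peak_channel: Optional[str] = None
    peak_time: Optional[float] = None
    r_effect: Optional[float] = None
    d_one_sample: Optional[float] = None
    d_regression: Optional[float] = None
    temporal_extent: Optional[float] = None   # s
    effect_size_formulas: dict = field(default_factory=lambda: {
        "r": "sign(t)*sqrt(t^2/(t^2+df))",
        "d_one_sample": "t/sqrt(n)",
        "d_regression": "2*t/sqrt(df)",
    })

    @property
    def n_members(self) -> int:
        return self.channels.size

    def member_mask(self, n_channels: int, n_times: int) -> np.ndarray:
        m = np.zeros((n_channels, n_times), dtype=bool)
        m[self.channels, self.time_indices] = True
        return m


def forming_threshold(df: int, forming_alpha: float) -> float:
    """Student-t quantile at the per-tail forming probability."""
    return float(stats.t.ppf(1.0 - forming_alpha, df))


def form_clusters(stat_map: StatMap, adjacency: AdjacencyGraph,
                  forming_alpha: float, tail: int) -> list[ClusterResult]:
    """Suprathreshold connected components on one tail, |mass|-descending."""
    if tail not in (1, -1):
        raise ValueError("tail must be +1 or -1")
    thresh = forming_threshold(stat_map.df, forming_alpha)
    tflat = stat_map.t.ravel()
    edges = spatiotemporal_edges(adjacency, stat_map.times.size)
    mask = tflat > thresh if tail > 0 else tflat < -thresh
    idx, labels = _components(mask, tflat, edges)
    clusters = []
    T = stat_map.times.size
    for lab in range(labels.max() + 1 if labels.size else 0):
        members = idx[labels == lab]
        clusters.append(ClusterResult(
            tail=tail, channels=members // T, time_indices=members % T,
            mass=float(tflat[members].sum())))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _all_sign_assignments(n: int) -> np.ndarray:
    if n > _EXHAUSTIVE_MAX:
        raise ValueError(f"exhaustive enumeration limited to {_EXHAUSTIVE_MAX} "
                         "participants")
    bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    return 2.0 * bits - 1.0


def permutation_null(binned: BinnedData, regressor: DesignRegressor,
                     adjacency: AdjacencyGraph, *, n_perm: int,
                     forming_alpha: float, seed=0,
                     exhaustive: Optional[bool] = None
                     ) -> dict[int, np.ndarray]:
    """Per-tail max-cluster-mass null distributions.

    Intercept regressors use participant sign flips of the full PGI
    (all bins, channels, times); covariates shuffle whole participants'
    regressor row-blocks.  ``exhaustive=None`` auto-enables full sign
    enumeration when 2^n_participants <= n_perm.
    """
    _check_alignment(binned, regressor)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small for Monte-Carlo inference",
                      stacklevel=2)
    Y = _flatten_pgi(binned)
    P = len(binned.participants)
    B = len(binned.bin_labels)
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    edges = spatiotemporal_edges(adjacency, binned.times.size)

    if regressor.kind == "intercept":
        df = n - 1
        if exhaustive is None:
            exhaustive = P <= _EXHAUSTIVE_MAX and 2**P <= n_perm
        if exhaustive:
            signs = _all_sign_assignments(P)
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, P))
        S = np.tile(signs, (1, B))                       # rows are bin-major
        means = (S @ Y) / n
        ss = (Y**2).sum(axis=0)
        var = (ss[None, :] - n * means**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tmaps = means / np.sqrt(var / n)
        bad = ~np.isfinite(tmaps)
        tmaps[bad] = np.sign(means[bad]) * T_CAP
        np.clip(tmaps, -T_CAP, T_CAP, out=tmaps)
    else:
        df = n - 2
        perms = np.stack([rng.permutation(P) for _ in range(n_perm)])
        grid = regressor.grid()                          # (B, P)
        X = grid[:, perms].transpose(1, 0, 2).reshape(n_perm, n)
        Xc = X - X.mean(axis=1, keepdims=True)
        sx = np.linalg.norm(Xc[0])
        if sx == 0:
            raise ValueError("regressor is constant")
        Yc = Y - Y.mean(axis=0)
        sy = np.linalg.norm(Yc, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc @ Yc) / (sx * sy)
        r[~np.isfinite(r)] = 0.0
        with np.errstate(divide="ignore"):
            tmaps = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
        np.clip(tmaps, -T_CAP, T_CAP, out=tmaps)

    thresh = forming_threshold(df, forming_alpha)
    null = {1: np.empty(tmaps.shape[0]), -1: np.empty(tmaps.shape[0])}
    for i in range(tmaps.shape[0]):
        row = tmaps[i]
        null[1][i] = _max_mass(row, thresh, 1, edges)
        null[-1][i] = _max_mass(row, thresh, -1, edges)
    return null


def cluster_pvalues(clusters: list[ClusterResult],
                    null: dict[int, np.ndarray]) -> list[ClusterResult]:
    """Monte-Carlo p = (b + 1) / (m + 1) against the cluster's own tail.

    Ties are counted with a small relative tolerance so a permutation
    reproducing the observed mass (e.g. the identity assignment under
    exhaustive enumeration) is not lost to round-off.
    """
    for c in clusters:
        dist = null[c.tail]
        m = abs(c.mass)
        b = int((dist >= m - 1e-9 * max(m, 1.0)).sum())
        c.p_value = (b + 1) / (dist.size + 1)
    return clusters


def effect_sizes(stat_map: StatMap, cluster: ClusterResult,
                 n: int, df: int) -> tuple[float, float, float]:
    """(r, d_one_sample, d_regression) at the cluster's peak |t| sample."""
    if cluster.n_members == 0:
        raise ValueError("empty cluster")
    if df <= 0:
        raise ValueError("df must be positive")
    tv = stat_map.t[cluster.channels, cluster.time_indices]
    t_peak = tv[np.abs(tv).argmax()]
    r = np.sign(t_peak) * np.sqrt(t_peak**2 / (t_peak**2 + df))
    return float(r), float(t_peak / np.sqrt(n)), float(2 * t_peak / np.sqrt(df))


def select_peak_electrode(cluster: ClusterResult, stat_map: StatMap) -> str:
    """Electrode with the most member timepoints in the cluster.

    Ties break by larger summed |t| over members, then by channel name.
    """
    if cluster.n_members == 0:
        raise ValueError("empty cluster")
    tv = np.abs(stat_map.t[cluster.channels, cluster.time_indices])
    member_chs = sorted(np.unique(cluster.channels),
                        key=lambda ch: stat_map.ch_names[ch])
    best_key, best_ch = None, None
    for ch in member_chs:   # name-ascending, so strict > keeps the first on ties
        sel = cluster.channels == ch
        key = (int(sel.sum()), float(tv[sel].sum()))
        if best_key is None or key > best_key:
            best_key, best_ch = key, ch
    return stat_map.ch_names[best_ch]


@dataclass
class MuaResult:
    """Everything one (scheme, regressor) analysis produced."""

    scheme: str
    regressor_name: str
    stat_map: StatMap
    clusters: list[ClusterResult]
    null: dict[int, np.ndarray]
    n_perm: int
    forming_alpha: float
    alpha: float

    def significant(self) -> list[ClusterResult]:
        return [c for c in self.clusters if c.p_value is not None
                and c.p_value <= self.alpha]


def run_mua(pgi: BinnedData, regressors: dict[str, DesignRegressor],
            adjacency: AdjacencyGraph, *, window: tuple[float, float] = (0.5, 3.0),
            forming_alpha: float = 0.025, alpha: float = 0.05,
            n_perm: int = 10_000, seed=0,
            exhaustive: Optional[bool] = None) -> dict[str, MuaResult]:
    """Full inference for each regressor over the analysis window.

    Restricts the PGI to the window (default 0.5-3.0 s, the DC-shift
    period), fits the sample-wise statistics, forms clusters on both
    tails, builds the permutation null, attaches Monte-Carlo p-values,
    effect sizes and the peak electrode/time.
    """
    win = pgi.restrict_window(window)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(regressors))
    results: dict[str, MuaResult] = {}
    for (name, reg), sub_seed in zip(regressors.items(), seeds):
        sm = samplewise_stat(win, reg)
        clusters = form_clusters(sm, adjacency, forming_alpha, 1) \
            + form_clusters(sm, adjacency, forming_alpha, -1)
        null = permutation_null(win, reg, adjacency, n_perm=n_perm,
                                forming_alpha=forming_alpha, seed=sub_seed,
                                exhaustive=exhaustive)
        cluster_pvalues(clusters, null)
        for c in clusters:
            c.r_effect, c.d_one_sample, c.d_regression = effect_sizes(
                sm, c, sm.n_obs, sm.df)
            c.peak_channel = select_peak_electrode(c, sm)
            tv = sm.t[c.channels, c.time_indices]
            c.peak_time = float(sm.times[c.time_indices[np.abs(tv).argmax()]])
            span = sm.times[c.time_indices]
            c.temporal_extent = float(span.max() - span.min())
        clusters.sort(key=lambda c: (c.p_value, -abs(c.mass)))
        results[name] = MuaResult(pgi.scheme, name, sm, clusters, null,
                                  n_perm, forming_alpha, alpha)
        log.info("MUA %s/%s: %d clusters, min p=%s", pgi.scheme, name,
                 len(clusters),
                 min((c.p_value for c in clusters), default=None))
    return results
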