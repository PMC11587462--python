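"""Shared fixtures and independent oracles for the test suite.

The oracles here (flood-fill clustering, exhaustive sign-flip
enumeration) are deliberately written from scratch, without touching
the package's cluster engine, so tests compare two independent routes
to the same quantity.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from patternglare.config import AnalysisConfig, SimulationConfig
from patternglare.containers import BinnedData
from patternglare.layouts import DEFAULT_4, DEFAULT_16, subset_layout
from patternglare.mua import build_adjacency


@pytest.fixture
def tiny_layout():
    return subset_layout(DEFAULT_4)


@pytest.fixture
def small_layout():
    return subset_layout(DEFAULT_16)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


@pytest.fixture
def small_sim():
    """A fast, fully featured simulated-study configuration."""
    return SimulationConfig(
        n_participants=8, channels=list(DEFAULT_16), sfreq=32.0,
        epoch_window=(-0.25, 3.5), noise_sd=8.0, dc_amplitude=2.0,
        factor_effect_gain=2.0, seed=11)


@pytest.fixture
def noise_free_sim():
    return SimulationConfig(
        n_participants=4, channels=list(DEFAULT_4), sfreq=32.0,
        epoch_window=(-0.25, 3.5), noise_sd=0.0, dc_amplitude=2.0,
        factor_effect_gain=1.0, lambda_partition=0.5, lambda_onset=0.5,
        seed=5)


@pytest.fixture
def fast_analysis():
    return AnalysisConfig(filter_high=12.0, n_perm=200, n_boot=200, seed=3)


def make_pgi_binned(values: np.ndarray, layout, sfreq: float = 50.0,
                    t0: float = 0.5, scheme: str = "onsets_2_8",
                    bin_labels=("onsets_2_8",)) -> BinnedData:
    """Wrap a (P, B, C, T) array as single-condition PGI BinnedData."""
    if values.ndim == 4:
        values = values[:, :, None]
    P, B, _, C, T = values.shape
    parts = tuple(f"P{i + 1:02d}" for i in range(P))
    times = t0 + np.arange(T) / sfreq
    return BinnedData(scheme=scheme, values=values,
                      counts=np.ones((P, B, 1), dtype=int),
                      participants=parts, bin_labels=tuple(bin_labels),
                      conditions=("PGI",), sfreq=sfreq, times=times,
                      ch_names=layout.names, ch_pos=layout.pos)


# ---------------------------------------------------------------------------
# independent oracles

def oracle_clusters(tmap: np.ndarray, thresh: float, tail: int,
                    neighbor: np.ndarray) -> list[dict]:
    """Flood-fill clustering over (channel, time), spatial + temporal links."""
    C, T = tmap.shape
    mask = tmap > thresh if tail > 0 else tmap < -thresh
    seen = np.zeros_like(mask)
    out = []
    for c0 in range(C):
        for t0 in range(T):
            if not mask[c0, t0] or seen[c0, t0]:
                continue
            stack, members = [(c0, t0)], []
            seen[c0, t0] = True
            while stack:
                c, t = stack.pop()
                members.append((c, t))
                for c2 in range(C):
                    if neighbor[c, c2] and mask[c2, t] and not seen[c2, t]:
                        seen[c2, t] = True
                        stack.append((c2, t))
                for t2 in (t - 1, t + 1):
                    if 0 <= t2 < T and mask[c, t2] and not seen[c, t2]:
                        seen[c, t2] = True
                        stack.append((c, t2))
            out.append({"members": frozenset(members),
                        "mass": float(sum(tmap[c, t] for c, t in members))})
    return out


def oracle_one_sample_t(Y: np.ndarray) -> np.ndarray:
    """t map for participant x channel x time data, mean against zero."""
    n = Y.shape[0]
    return Y.mean(0) / (Y.std(0, ddof=1) / np.sqrt(n))


def oracle_exhaustive_signflip_p(Y: np.ndarray, forming_alpha: float,
                                 neighbor: np.ndarray) -> list[dict]:
    """Exact sign-flip cluster p-values by full enumeration.

    ``Y`` is participant x channel x time.  Returns the observed
    clusters of both tails with p = (b + 1) / (2^n + 1).
    """
    n = Y.shape[0]
    thresh = stats.t.ppf(1 - forming_alpha, n - 1)
    null = {1: [], -1: []}
    for k in range(2**n):
        signs = np.array([1.0 if (k >> i) & 1 else -1.0 for i in range(n)])
        tm = oracle_one_sample_t(Y * signs[:, None, None])
        for tail in (1, -1):
            cl = oracle_clusters(tm, thresh, tail, neighbor)
            null[tail].append(max((abs(c["mass"]) for c in cl), default=0.0))
    obs_t = oracle_one_sample_t(Y)
    results = []
    for tail in (1, -1):
        for c in oracle_clusters(obs_t, thresh, tail, neighbor):
            b = sum(1 for m in null[tail]
                    if m >= abs(c["mass"]) - 1e-9 * max(abs(c["mass"]), 1.0))
            results.append({"tail": tail, "members": c["members"],
                            "mass": c["mass"], "p": (b + 1) / (2**n + 1)})
    return results


@pytest.fixture
def tiny_adjacency(tiny_layout):
    return build_adjacency(tiny_layout, 1.2)
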