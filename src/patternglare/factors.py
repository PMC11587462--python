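"""Behavioral factor analysis: discomfort index, varimax factors, GSM.

Seven measures per participant (CHi total, VDS total, headache
frequency / intensity / duration, sensory aura, and the in-experiment
discomfort index) are standardised and reduced to three varimax-rotated
factors, characterised as visual stress, headache and discomfort by the
measure block each loads on.  Factor scores use the regression (Thomson)
method.  The Gram-Schmidt orthogonaliser defined here (projection
removal only, no normalisation) is the one used throughout the design
regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "discomfort_index", "standardize", "extract_factors", "label_factors",
    "gram_schmidt", "varimax", "score_participants", "FactorScores",
    "MEASURE_GROUPS",
]

#: measure blocks used to characterise factors
MEASURE_GROUPS = {
    "visual_stress": ("chi_total", "vds_total"),
    "headache": ("headache_freq", "headache_intensity", "headache_duration",
                 "sensory_aura"),
    "discomfort": ("discomfort_index",),
}

FACTOR_ORDER = ("visual_stress", "headache", "discomfort")


def discomfort_index(trials: pd.DataFrame) -> pd.Series:
    """Mean medium rating minus the mean of the pooled thin/thick ratings.

    Ratings are taken per trial (each trial carries one rating repeated
    across its onset rows), across all blocks.  Positive values identify
    participants who found the medium grating more uncomfortable than
    the controls.
    """
    per_trial = trials.drop_duplicates(
        subset=["participant", "stimulus", "partition", "trial"])
    out = {}
    for p, sub in per_trial.groupby("participant", sort=True):
        med = sub.loc[sub["stimulus"] == "medium", "rating"]
        ctrl = sub.loc[sub["stimulus"].isin(["thin", "thick"]), "rating"]
        if med.empty or sub.loc[sub["stimulus"] == "thin"].empty \
                or sub.loc[sub["stimulus"] == "thick"].empty:
            raise ValueError(f"participant {p} is missing a stimulus type")
        out[p] = med.mean() - ctrl.mean()
    return pd.Series(out, name="discomfort_index").rename_axis("participant")


def standardize(measures: pd.DataFrame) -> pd.DataFrame:
    """z-score every column (sample SD, n-1 denominator)."""
    sd = measures.std(ddof=1)
    flat = sd[~(sd > 0)].index.tolist()
    if flat:
        raise ValueError(f"zero-variance measure(s): {flat}")
    return (measures - measures.mean()) / sd


def varimax(loadings: np.ndarray, max_iter: int = 500,
            tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation, started from the identity (deterministic).

    Returns ``(rotated_loadings, rotation_matrix)``.  Raises on
    non-convergence, reporting the iteration count.
    """
    p, k = loadings.shape
    R = np.eye(k)
    crit = 0.0
    for it in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L**3 - (1.0 / p) * L @ np.diag(np.diag(L.T @ L))))
        R = u @ vt
        new = s.sum()
        if new <= crit * (1.0 + tol):
            return loadings @ R, R
        crit = new
    raise RuntimeError(f"varimax rotation did not converge in {max_iter} iterations")


@dataclass
class FactorScores:
    """Varimax factor solution with regression-method scores."""

    scores: pd.DataFrame        # participant x factor, columns mean 0
    loadings: pd.DataFrame      # measure x factor
    eigenvalues: np.ndarray     # of the measure correlation matrix, descending

    def labeled(self, mapping: dict[str, str]) -> "FactorScores":
        """Rename factor columns according to a label mapping."""
        order = [c for c in FACTOR_ORDER if c in mapping.values()]
        scores = self.scores.rename(columns=mapping)[order]
        loadings = self.loadings.rename(columns=mapping)[order]
        return FactorScores(scores, loadings, self.eigenvalues)


def extract_factors(z_table: pd.DataFrame, k: int = 3) -> FactorScores:
    """Principal-component ``k``-factor solution with varimax rotation.

    Unrotated loadings are the top-``k`` eigenvectors of the measure
    correlation matrix scaled by the root eigenvalues (principal
    component factoring), which keeps single-indicator factors — such
    as a factor carried almost entirely by the in-experiment discomfort
    index — identifiable.  Scores are computed by the regression
    (Thomson) method, ``S = Z R^{-1} Lambda`` with ``R`` the measure
    correlation matrix.  The sign of each factor is fixed so its
    largest-magnitude loading is positive.  The full eigenvalue
    sequence of ``R`` is returned for scree inspection.
    """
    n, m = z_table.shape
    if n <= m:
        raise ValueError("need more participants than measures")
    Z = z_table.to_numpy()
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order_ev = np.argsort(evals)[::-1]
    eigenvalues = evals[order_ev]
    L0 = evecs[:, order_ev[:k]] * np.sqrt(np.maximum(eigenvalues[:k], 0.0))
    L, _ = varimax(L0)

    # order factors by explained common variance, fix signs
    order = np.argsort(-(L**2).sum(axis=0))
    L = L[:, order]
    signs = np.sign(L[np.abs(L).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    L = L * signs

    # pseudo-inverse: rank-deficient correlation matrices (e.g. noise-free
    # block structure) are handled gracefully, full rank matches solve()
    S = Z @ (np.linalg.pinv(corr, hermitian=True) @ L)
    cols = [f"factor{i + 1}" for i in range(k)]
    scores = pd.DataFrame(S - S.mean(axis=0), index=z_table.index, columns=cols)
    loadings = pd.DataFrame(L, index=z_table.columns, columns=cols)
    return FactorScores(scores, loadings, eigenvalues)


def label_factors(loadings: pd.DataFrame,
                  groups: dict[str, tuple[str, ...]] = MEASURE_GROUPS
                  ) -> dict[str, str]:
    """Assign {visual_stress, headache, discomfort} labels to factors.

    Each factor is labelled by the measure group with the largest mean
    absolute loading, assigned greedily (best match first) so the
    mapping is bijective; a conflict raises.
    """
    if loadings.shape[1] != len(groups):
        raise ValueError("need exactly one factor per label")
    strength = pd.DataFrame(
        {lab: loadings.loc[list(members)].abs().mean()
         for lab, members in groups.items()})   # factor x label
    mapping: dict[str, str] = {}
    avail_f = set(strength.index)
    avail_l = set(strength.columns)
    while avail_l:
        cands = [(strength.at[f, lab], f, lab)
                 for f in avail_f for lab in avail_l]
        vmax = max(v for v, _, _ in cands)
        top = [(f, lab) for v, f, lab in cands if v == vmax]
        # ties are only ambiguous when the tied candidates compete for the
        # same factor or the same label
        fs_, ls_ = [f for f, _ in top], [lab for _, lab in top]
        if len(set(fs_)) < len(fs_) or len(set(ls_)) < len(ls_):
            raise ValueError(f"ambiguous assignment: tied best matches {top}")
        f, lab = top[0]
        mapping[f] = lab
        avail_f.discard(f)
        avail_l.discard(lab)
    return mapping


def score_participants(behavioral: pd.DataFrame, k: int = 3) -> FactorScores:
    """Standardise, extract, rotate and label in one step."""
    z = standardize(behavioral)
    fs = extract_factors(z, k=k)
    return fs.labeled(label_factors(fs.loadings))


def gram_schmidt(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Sequential projection removal in the given order.

    ``out[0]`` is the first input unchanged; each later vector has its
    projections onto all earlier *outputs* removed.  Lengths are not
    normalised.  A vector whose residual collapses to numerical zero
    (collinearity) raises, reporting its index.
    """
    vecs = [np.asarray(v, dtype=float) for v in vectors]
    if not vecs:
        return []
    length = vecs[0].shape
    if any(v.shape != length for v in vecs):
        raise ValueError("all vectors must have the same length")
    if np.linalg.norm(vecs[0]) == 0:
        raise ValueError("first vector is zero")
    out: list[np.ndarray] = []
    for i, v in enumerate(vecs):
        r = v.copy()
        for u in out:
            r -= (r @ u) / (u @ u) * u
        if i > 0 and np.linalg.norm(r) <= 1e-12 * max(np.linalg.norm(v), 1.0):
            raise ValueError(f"vector {i} is collinear with its predecessors")
        out.append(r)
    return out
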