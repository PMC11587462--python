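"""End-to-end pipeline: simulate -> preprocess -> factors -> MUA -> report.

This module wires the stage modules together in the order the analysis
protocol prescribes and is what both the command-line interface and the
reproduction script drive.  Analyses are named by ``(scheme, regressor
spec)`` pairs, where the regressor spec is one of::

    intercept
    factor:<name>                         basic per-participant factor scores
    twoway:<name>:<direction>             factor x exponential change (3 bins)
    threeway:<name>:<onset_dir>:<part_dir>  factor x onset-pair x partition

Interaction regressors are always built for all three factors in the
fixed order visual stress, headache, discomfort and (by default)
Gram-Schmidt orthogonalised before the requested factor's regressor is
used, mirroring how the factor set was treated as a family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig, SimulationConfig
from .containers import BinnedData, scheme_bins
from .factors import FACTOR_ORDER, FactorScores, score_participants
from .mua import MuaResult, build_adjacency, run_mua
from .preprocessing import (bandpass_filter, baseline_correct, bin_average,
                            compute_pgi, decimate, include_participants,
                            reject_threshold, rereference_average)
from .regressors import (DesignRegressor, exponential_weights, factor_regressor,
                         intercept_regressor, orthogonalize_design,
                         three_way_regressor, two_way_regressor)
from .synthetic import SimulatedStudy, simulate_study

__all__ = ["DEFAULT_ANALYSES", "PipelineResult", "run_pipeline",
           "build_scheme_regressors", "preprocess_epochs"]

log = logging.getLogger(__name__)

DEFAULT_ANALYSES: list[tuple[str, str]] = [
    ("onsets_2_8", "intercept"),
    ("onsets_2_8", "factor:discomfort"),
    ("partitions", "twoway:discomfort:decrease"),
    ("partitions", "twoway:discomfort:increase"),
    ("onset_pairs", "twoway:discomfort:decrease"),
    ("onset_pairs", "twoway:discomfort:increase"),
    ("partition_by_onset_pair", "threeway:discomfort:decrease:increase"),
]


def build_scheme_regressors(spec: str, scheme: str, scores: pd.DataFrame,
                            lam: float, orthogonalize: bool) -> DesignRegressor:
    """Build the regressor a spec string asks for, on the given scores.

    ``scores`` is participant x factor (visual_stress, headache,
    discomfort), already restricted and ordered to match the binned
    data's participants.
    """
    bin_labels = tuple(lbl for lbl, _, _ in scheme_bins(scheme))
    parts = spec.split(":")
    kind = parts[0]
    if kind == "intercept":
        return intercept_regressor(tuple(scores.index), bin_labels)
    if kind == "factor":
        return factor_regressor(scores[parts[1]], parts[1], bin_labels)
    if kind == "twoway":
        factor, direction = parts[1], parts[2]
        pattern = exponential_weights(len(bin_labels), direction, lam)
        regs = [two_way_regressor(scores[f], pattern, bin_labels, f,
                                  granularity=scheme) for f in FACTOR_ORDER]
        if orthogonalize:
            regs = orthogonalize_design(regs)
        return regs[FACTOR_ORDER.index(factor)]
    if kind == "threeway":
        factor, onset_dir, part_dir = parts[1], parts[2], parts[3]
        op = exponential_weights(3, onset_dir, lam)
        pp = exponential_weights(3, part_dir, lam)
        regs = [three_way_regressor(scores[f], op, pp, bin_labels, f)
                for f in FACTOR_ORDER]
        if orthogonalize:
            regs = orthogonalize_design(regs)
        return regs[FACTOR_ORDER.index(factor)]
    raise ValueError(f"unknown regressor spec: {spec!r}")


def preprocess_epochs(epochs, trials, ana: AnalysisConfig):
    """Filter, decimate, re-reference, baseline, reject, include."""
    if ana.filter_low is not None or ana.filter_high is not None:
        epochs = bandpass_filter(epochs, ana.filter_low, ana.filter_high)
    if ana.decimate > 1:
        epochs = decimate(epochs, ana.decimate)
    epochs = rereference_average(epochs)
    epochs = baseline_correct(epochs)
    rej = reject_threshold(epochs, ana.reject_limit, trials)
    included = include_participants(rej.trials, ana.min_usable)
    return rej.epochs, rej.trials, included, rej.log


@dataclass
class PipelineResult:
    """Everything a full pipeline run produced."""

    study: SimulatedStudy
    trials: pd.DataFrame                       # post-rejection usable flags
    included: list
    factor_scores: FactorScores
    binned: dict[str, BinnedData]              # per-condition data per scheme
    pgi: dict[str, BinnedData]                 # complete-participant PGI per scheme
    regressors: dict[str, DesignRegressor]     # keyed "<scheme>|<spec>"
    mua: dict[str, MuaResult]
    rejection_log: pd.DataFrame = field(repr=False, default=None)


def run_pipeline(sim: SimulationConfig, ana: AnalysisConfig,
                 analyses: list[tuple[str, str]] | None = None
                 ) -> PipelineResult:
    """Simulate one study and run the requested analyses on it."""
    sim.validate()
    ana.validate()
    if analyses is None:
        analyses = DEFAULT_ANALYSES

    study = simulate_study(sim)
    epochs, trials, included, rej_log = preprocess_epochs(
        study.epochs, study.trials, ana)
    log.info("included %d/%d participants", len(included), sim.n_participants)

    behavioral = study.behavioral.loc[included]
    fscores = score_participants(behavioral)

    layout = sim.layout()
    adjacency = build_adjacency(layout, ana.distance_threshold)
    schemes = sorted({s for s, _ in analyses})
    binned: dict[str, BinnedData] = {}
    pgi: dict[str, BinnedData] = {}
    for scheme in schemes:
        b = bin_average(epochs, trials, scheme, participants=included)
        p = compute_pgi(b).drop_incomplete()
        binned[scheme] = b
        pgi[scheme] = p
        if len(p.participants) < len(included):
            log.info("scheme %s: %d participants with complete cells",
                     scheme, len(p.participants))

    regressors: dict[str, DesignRegressor] = {}
    mua: dict[str, MuaResult] = {}
    seeds = np.random.SeedSequence(ana.seed).spawn(len(analyses))
    for (scheme, spec), sub_seed in zip(analyses, seeds):
        p = pgi[scheme]
        scores = fscores.scores.loc[list(p.participants)]
        reg = build_scheme_regressors(spec, scheme, scores,
                                      ana.lambda_regressor, ana.orthogonalize)
        key = f"{scheme}|{spec}"
        regressors[key] = reg
        res = run_mua(p, {key: reg}, adjacency, window=ana.window,
                      forming_alpha=ana.forming_alpha, alpha=ana.alpha,
                      n_perm=ana.n_perm, seed=sub_seed)[key]
        if ana.refine_borderline and any(
                c.p_value is not None and abs(c.p_value - ana.alpha) <= 0.02
                for c in res.clusters):
            log.info("%s: borderline p, refining with %d permutations",
                     key, ana.n_perm_refine)
            res = run_mua(p, {key: reg}, adjacency, window=ana.window,
                          forming_alpha=ana.forming_alpha, alpha=ana.alpha,
                          n_perm=ana.n_perm_refine, seed=sub_seed)[key]
        mua[key] = res

    return PipelineResult(study=study, trials=trials, included=included,
                          factor_scores=fscores, binned=binned, pgi=pgi,
                          regressors=regressors, mua=mua, rejection_log=rej_log)
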