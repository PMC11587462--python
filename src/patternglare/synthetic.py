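"""Synthetic pattern-glare study generator with fully known ground truth.

The generator emulates the study design end to end: per participant,
three blocks (partitions) x three grating types (thin / medium / thick)
x six trials, each trial a train of 7-9 three-second onsets of the same
stimulus, one epoch per onset.  Medium-stimulus epochs carry a sustained
positivity ("DC shift") over a posterior raised-cosine topography during
the DC window; its amplitude for participant ``p`` in partition ``j``
and onset-pair ``i`` is

    A(p, j, i) = dc_amplitude
               + factor_effect_gain * s_p * exp(-lambda_partition*(j-1))
                                          * exp(+lambda_onset*(i-1))

where ``s_p`` is the participant's true discomfort factor score: an
exponential habituation across partitions and sensitisation across
onset-pairs, modulated by discomfort.  Thin/thick epochs carry no
injected effect.  Noise is stationary Gaussian, AR(1) in time with an
exponential spatial covariance over the electrode layout.

Onset-pair index: onsets {2,3} -> 1, {4,5} -> 2, {6,7} -> 3 and
{8,9} -> 4 (the exponential law extrapolated one step; onsets 1, 8, 9
never enter an onset-pair analysis bin).  Onset 1 uses pair index 1; it
is excluded from every analysis bin regardless.

Ground truth (factor scores, effect support, per-bin amplitudes,
artifact ledger) is returned for recovery testing.  The reported effect
support counts channels whose topography weight is at least 10% of the
peak weight; the raised-cosine tail below that carries negligible
signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.signal import lfilter

from .config import STIMULI, SimulationConfig
from .containers import EpochsVolume

__all__ = [
    "SyntheticTruth", "SimulatedStudy",
    "simulate_epochs", "simulate_behavioral", "simulate_study",
    "onset_pair_index",
]

SUPPORT_WEIGHT_FLOOR = 0.1

#: questionnaire loading matrix, columns (visual_stress, headache, discomfort)
QUESTIONNAIRE_LOADINGS = pd.DataFrame(
    {
        "visual_stress": [0.85, 0.80, 0.10, 0.10, 0.05, 0.15],
        "headache": [0.10, 0.15, 0.85, 0.80, 0.75, 0.70],
        "discomfort": [0.20, 0.20, 0.05, 0.10, 0.10, 0.10],
    },
    index=["chi_total", "vds_total", "headache_freq",
           "headache_intensity", "headache_duration", "sensory_aura"],
)

#: affine (offset, scale) giving each questionnaire its native range
_MEASURE_SCALES = {
    "chi_total": (20.0, 8.0),
    "vds_total": (60.0, 25.0),
    "headache_freq": (5.0, 3.0),
    "headache_intensity": (4.0, 2.0),
    "headache_duration": (10.0, 6.0),
    "sensory_aura": (2.0, 1.0),
}

FACTOR_NAMES = ("visual_stress", "headache", "discomfort")


def onset_pair_index(onset: int) -> int:
    """Map an onset index (1..9) to its onset-pair index (1..4)."""
    if onset < 1:
        raise ValueError("onset indices start at 1")
    return max(1, onset // 2)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study."""

    factor_scores: pd.DataFrame        # participant x (visual_stress, headache, discomfort)
    effect_support: np.ndarray         # (n_channels, n_times) bool
    topography: np.ndarray             # (n_channels,) weights in [0, 1]
    bin_amplitudes: np.ndarray         # (P, n_partitions, 3): total medium amplitude
    factor_amplitudes: np.ndarray      # (P, n_partitions, 3): factor-driven part only
    dc_amplitude: float
    artifact_epochs: np.ndarray        # global epoch indices given injected spikes

    @property
    def discomfort(self) -> pd.Series:
        return self.factor_scores["discomfort"]


class SimulatedStudy(NamedTuple):
    epochs: EpochsVolume
    trials: pd.DataFrame
    behavioral: pd.DataFrame
    truth: SyntheticTruth


def _topography(config: SimulationConfig) -> np.ndarray:
    layout = config.layout()
    if config.effect_topography is not None:
        return np.asarray(config.effect_topography, dtype=float)
    center = layout.pos[layout.index(config.effect_center)]
    dist = np.sqrt(((layout.pos - center) ** 2).sum(1))
    w = np.where(dist < config.effect_radius,
                 0.5 * (1.0 + np.cos(np.pi * dist / config.effect_radius)), 0.0)
    return w


def _bin_amplitude_tables(config: SimulationConfig, scores: np.ndarray):
    j = np.arange(config.n_partitions)
    i = np.arange(3)
    change = np.exp(-config.lambda_partition * j)[:, None] \
        * np.exp(config.lambda_onset * i)[None, :]
    factor_part = config.factor_effect_gain * scores[:, None, None] * change[None]
    return config.dc_amplitude + factor_part, factor_part


def _epoch_amplitudes(config: SimulationConfig, trials: pd.DataFrame,
                      scores: pd.Series) -> np.ndarray:
    """Total injected medium amplitude for every epoch row (0 for controls)."""
    med = (trials["stimulus"] == "medium").to_numpy()
    part = trials["partition"].to_numpy()
    pair = trials["onset"].map(onset_pair_index).to_numpy()
    s = scores.reindex(trials["participant"]).to_numpy()
    amp = config.dc_amplitude + config.factor_effect_gain * s \
        * np.exp(-config.lambda_partition * (part - 1)) \
        * np.exp(config.lambda_onset * (pair - 1))
    return np.where(med, amp, 0.0)


def _simulate_noise(rng: np.random.Generator, n_epochs: int, n_times: int,
                    chol_spatial: Optional[np.ndarray], ar: float,
                    sd: float) -> np.ndarray:
    """Stationary AR(1)-in-time noise with spatial mixing, (E, C, T) in uV."""
    n_ch = chol_spatial.shape[0] if chol_spatial is not None else 1
    w = rng.standard_normal((n_epochs, n_times, n_ch))
    if ar > 0:
        # first sample at full marginal SD keeps the process stationary
        w[:, 1:, :] *= np.sqrt(1.0 - ar**2)
        w = lfilter([1.0], [1.0, -ar], w, axis=1)
    if chol_spatial is not None:
        w = w @ chol_spatial.T
    return sd * np.transpose(w, (0, 2, 1))


def simulate_epochs(config: SimulationConfig):
    """Generate epoched EEG, the trial table and the ground truth.

    Returns ``(epochs, trials, truth)``.  One epoch per stimulus onset;
    identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    layout = config.layout()
    n_ch = len(layout)
    times = config.times()
    n_times = times.size
    participants = [f"P{p + 1:02d}" for p in range(config.n_participants)]

    scores = rng.standard_normal((config.n_participants, 3))
    factor_scores = pd.DataFrame(scores, index=pd.Index(participants, name="participant"),
                                 columns=list(FACTOR_NAMES))

    onset_counts = np.array(sorted(config.onset_distribution), dtype=int)
    onset_probs = np.array([config.onset_distribution[k] for k in onset_counts])

    rows = []
    epoch_id = 0
    for p in participants:
        s_disc = factor_scores.loc[p, "discomfort"]
        for partition in range(1, config.n_partitions + 1):
            for stim in STIMULI:
                for trial in range(1, config.trials_per_stimulus_per_partition + 1):
                    n_on = int(rng.choice(onset_counts, p=onset_probs))
                    latent = config.rating_base \
                        + config.rating_gain * s_disc * (stim == "medium") \
                        + config.rating_noise_sd * rng.standard_normal()
                    rating = int(np.clip(np.rint(latent), 1, 5))
                    for onset in range(1, n_on + 1):
                        rows.append((p, stim, partition, trial, onset, rating,
                                     True, epoch_id))
                        epoch_id += 1
    trials = pd.DataFrame(rows, columns=["participant", "stimulus", "partition",
                                         "trial", "onset", "rating", "usable",
                                         "epoch"])

    n_epochs = len(trials)
    data = np.zeros((n_epochs, n_ch, n_times))

    chol_spatial = None
    if config.noise_sd > 0:
        if config.spatial_corr_length > 0 and n_ch > 1:
            corr = np.exp(-layout.distances() / config.spatial_corr_length)
            chol_spatial = cholesky(corr, lower=True)
        else:
            chol_spatial = np.eye(n_ch)
        # per-participant chunks keep peak memory bounded
        for p in participants:
            idx = trials.index[trials["participant"] == p].to_numpy()
            data[idx] = _simulate_noise(rng, idx.size, n_times, chol_spatial,
                                        config.ar_coefficient, config.noise_sd)

    w = _topography(config)
    tmask = (times >= config.dc_window[0] - 1e-9) & (times <= config.dc_window[1] + 1e-9)
    amp = _epoch_amplitudes(config, trials, factor_scores["discomfort"])
    nz = np.flatnonzero(amp)
    if nz.size and w.any():
        data[np.ix_(nz, np.flatnonzero(w > 0), np.flatnonzero(tmask))] += \
            amp[nz, None, None] * w[w > 0][None, :, None]

    artifact_epochs = np.array([], dtype=int)
    if config.artifact_rate > 0:
        hit = np.flatnonzero(rng.random(n_epochs) < config.artifact_rate)
        spike_len = max(1, int(round(0.05 * config.sfreq)))
        for e in hit:
            ch = int(rng.integers(n_ch))
            t0 = int(rng.integers(0, n_times - spike_len + 1))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[e, ch, t0:t0 + spike_len] += sign * config.artifact_amplitude
        artifact_epochs = hit

    support = np.zeros((n_ch, n_times), dtype=bool)
    if w.max() > 0:
        support[np.ix_(w >= SUPPORT_WEIGHT_FLOOR * w.max(), tmask)] = True

    bin_amp, factor_amp = _bin_amplitude_tables(
        config, factor_scores["discomfort"].to_numpy())
    truth = SyntheticTruth(
        factor_scores=factor_scores,
        effect_support=support,
        topography=w,
        bin_amplitudes=bin_amp,
        factor_amplitudes=factor_amp,
        dc_amplitude=config.dc_amplitude,
        artifact_epochs=artifact_epochs,
    )
    epochs = EpochsVolume(data=data, sfreq=config.sfreq, tmin=config.epoch_window[0],
                          ch_names=layout.names, ch_pos=layout.pos)
    return epochs, trials, truth


def simulate_behavioral(config: SimulationConfig, truth: SyntheticTruth,
                        trials: pd.DataFrame) -> pd.DataFrame:
    """Seven questionnaire-style measures per participant.

    Six trait measures are loading-matrix combinations of the true
    factor scores plus independent noise, mapped onto questionnaire-like
    native ranges; the seventh, the discomfort index, is derived from
    the per-trial discomfort ratings (medium minus the mean of the
    pooled thin/thick ratings), making it a state measure tied to the
    discomfort factor.
    """
    if len(truth.factor_scores) != config.n_participants:
        raise ValueError("truth and config disagree on the number of participants")
    rng = np.random.default_rng([config.seed, 2_000_001])
    F = truth.factor_scores.to_numpy()
    L = QUESTIONNAIRE_LOADINGS.to_numpy()
    latent = F @ L.T + config.loading_noise_sd * rng.standard_normal(
        (config.n_participants, L.shape[0]))
    table = pd.DataFrame(index=truth.factor_scores.index)
    for k, name in enumerate(QUESTIONNAIRE_LOADINGS.index):
        off, scale = _MEASURE_SCALES[name]
        table[name] = off + scale * latent[:, k]
    # state measure: in-experiment discomfort index from the trial ratings
    from .factors import discomfort_index
    table["discomfort_index"] = discomfort_index(trials)
    return table


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full simulated study: epochs, trial table, behavioral table, truth."""
    epochs, trials, truth = simulate_epochs(config)
    behavioral = simulate_behavioral(config, truth, trials)
    return SimulatedStudy(epochs, trials, behavioral, truth)
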