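"""Configuration objects for simulation and analysis.

``SimulationConfig`` encodes the study design being emulated: three
blocks (partitions) with six trials per stimulus type per block, each
trial a train of 7-9 three-second onsets of the same grating, a
five-point discomfort rating after every trial, and a posterior
sustained ("DC-shift") positivity for the clinically relevant medium
grating whose amplitude habituates across partitions and sensitises
across onset-pairs in proportion to a participant's discomfort factor
score.

``AnalysisConfig`` holds every knob of the downstream pipeline: filter
band, artifact threshold, inclusion rule, analysis window, cluster
forming threshold, permutation and bootstrap counts, and the exponential
rate of the change-through-time regressors.

Both can be populated from a nested YAML mapping via :func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .layouts import Layout, biosemi32, subset_layout

__all__ = ["SimulationConfig", "AnalysisConfig", "load_config"]

STIMULI = ("thin", "medium", "thick")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic pattern-glare study.

    Amplitude parameters are in microvolts; rates are per bin step.
    ``effect_topography`` may be given explicitly (one weight in [0, 1]
    per channel); by default a raised-cosine bump of radius
    ``effect_radius`` centred on ``effect_center`` is used.
    """

    n_participants: int = 38
    channels: Optional[list[str]] = None       # None -> full 32-channel layout
    sfreq: float = 128.0                       # Hz
    epoch_window: tuple[float, float] = (-0.2, 4.0)   # s relative to onset
    n_partitions: int = 3
    trials_per_stimulus_per_partition: int = 6
    onset_distribution: dict[int, float] = field(
        default_factory=lambda: {7: 0.4, 8: 0.4, 9: 0.2})
    dc_amplitude: float = 2.0                  # uV medium-stimulus DC shift
    effect_center: str = "B16"
    effect_radius: float = 0.3                 # layout units
    effect_topography: Optional[np.ndarray] = None
    dc_window: tuple[float, float] = (0.5, 3.0)
    lambda_partition: float = 0.5              # habituation rate across partitions
    lambda_onset: float = 0.5                  # sensitisation rate across onset-pairs
    factor_effect_gain: float = 1.5            # uV per unit discomfort score
    noise_sd: float = 20.0                     # uV single-epoch noise
    ar_coefficient: float = 0.9                # temporal AR(1)
    spatial_corr_length: float = 0.5           # layout-distance units
    artifact_rate: float = 0.0                 # fraction of epochs given a spike
    artifact_amplitude: float = 150.0          # uV rectangular spike
    rating_base: float = 2.5                   # latent rating intercept
    rating_gain: float = 0.8                   # latent rating slope on discomfort score
    rating_noise_sd: float = 0.5
    loading_noise_sd: float = 0.4              # questionnaire uniqueness SD
    seed: int = 0

    def layout(self) -> Layout:
        if self.channels is None:
            return biosemi32()
        return subset_layout(self.channels)

    @property
    def n_times(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.sfreq)) + 1

    def times(self) -> np.ndarray:
        return self.epoch_window[0] + np.arange(self.n_times) / self.sfreq

    def validate(self) -> None:
        lay = self.layout()
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if len(lay) == 0:
            raise ValueError("empty channel layout")
        t0, t1 = self.epoch_window
        d0, d1 = self.dc_window
        if not (t0 < 0.0 < d0 < d1 <= t1):
            raise ValueError(
                "require epoch start < 0 < dc start < dc end <= epoch end, "
                f"got epoch {self.epoch_window}, dc {self.dc_window}")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        probs = np.array(list(self.onset_distribution.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("onset distribution must be a probability mass summing to 1")
        if any(k < 1 for k in self.onset_distribution):
            raise ValueError("onset counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.lambda_partition < 0 or self.lambda_onset < 0:
            raise ValueError("exponential rates must be >= 0")
        if self.effect_topography is not None:
            w = np.asarray(self.effect_topography, dtype=float)
            if w.shape != (len(lay),):
                raise ValueError("effect_topography must have one weight per channel")
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError("topography weights must lie in [0, 1]")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be in [0, 1]")


@dataclass
class AnalysisConfig:
    """Pipeline parameters, defaults mirroring the study protocol."""

    filter_low: Optional[float] = None     # Hz; None = no high-pass (epoched data)
    filter_high: Optional[float] = 30.0    # Hz low-pass edge
    decimate: int = 1
    reject_limit: float = 100.0            # uV artifact threshold
    min_usable: float = 0.2                # inclusion rule per condition
    window: tuple[float, float] = (0.5, 3.0)   # s, DC-shift analysis window
    forming_alpha: float = 0.025           # per-tail cluster-forming probability
    alpha: float = 0.05                    # per-tail FWE level
    n_perm: int = 10_000
    n_perm_refine: int = 25_000            # escalation for borderline p-values
    refine_borderline: bool = False
    n_boot: int = 5_000
    ci_level: float = 0.95
    lambda_regressor: float = 1.0          # exponential rate of change regressors
    orthogonalize: bool = True
    distance_threshold: float = 0.45       # adjacency edge rule, layout units
    report_p_cutoff: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.filter_low is not None and self.filter_high is not None \
                and not (0 < self.filter_low < self.filter_high):
            raise ValueError("need 0 < filter_low < filter_high")
        if self.decimate < 1:
            raise ValueError("decimate factor must be >= 1")
        if self.reject_limit <= 0:
            raise ValueError("reject_limit must be positive")
        if not (0.0 <= self.min_usable <= 1.0):
            raise ValueError("min_usable must be a proportion")
        if not (0.0 < self.forming_alpha < 0.5):
            raise ValueError("forming_alpha must be in (0, 0.5)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.lambda_regressor <= 0:
            raise ValueError("lambda_regressor must be > 0")


def _apply(dc, mapping):
    for key, value in (mapping or {}).items():
        if not hasattr(dc, key):
            raise KeyError(f"unknown config key: {key}")
        current = getattr(dc, key)
        if isinstance(current, tuple) and isinstance(value, (list, tuple)):
            value = tuple(value)
        if key == "onset_distribution":
            value = {int(k): float(v) for k, v in value.items()}
        setattr(dc, key, value)
    return dc


def load_config(path) -> tuple[SimulationConfig, AnalysisConfig]:
    """Load ``simulation:`` and ``analysis:`` sections from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = _apply(SimulationConfig(), raw.get("simulation"))
    ana = _apply(AnalysisConfig(), raw.get("analysis"))
    sim.validate()
    ana.validate()
    return sim, ana


def dump_config(sim: SimulationConfig, ana: AnalysisConfig, path) -> None:
    """Write both config sections back out as YAML."""
    sim_d = asdict(sim)
    if sim_d.get("effect_topography") is not None:
        sim_d["effect_topography"] = [float(x) for x in sim_d["effect_topography"]]
    payload = {"simulation": sim_d, "analysis": asdict(ana)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
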