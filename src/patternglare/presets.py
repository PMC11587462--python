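"""Benchmark study configurations at desk scale.

These presets pin down the simulated-study conditions used by the
package's validation computations (calibration, recovery, coverage), so
tests and reproduction scripts run the same experiment.  They are the
full study design — three blocks x six trials per stimulus x 7-9 onsets
— on a 16-channel posterior-weighted montage at a reduced sampling
rate, which keeps a single analysis in seconds while preserving the
0-30 Hz band the sustained response lives in.
"""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig, SimulationConfig
from .layouts import DEFAULT_16

__all__ = ["recovery_sim_config", "recovery_analysis_config",
           "RECOVERY_GAIN", "CELL_SD"]

#: single-epoch noise SD (uV) of the benchmark study
NOISE_SD = 10.0

#: epochs entering one partition cell: 6 trials x ~6.6 onsets in 2-8
EPOCHS_PER_CELL = 40

#: noise SD of the analysed per-cell averages
CELL_SD = NOISE_SD / np.sqrt(EPOCHS_PER_CELL)

#: discomfort gain of the injected effect: 3x the cell-level noise SD
RECOVERY_GAIN = 3.0 * CELL_SD


def recovery_sim_config(seed: int, with_effect: bool = True) -> SimulationConfig:
    """Scaled study with (or without) the discomfort x habituation effect."""
    return SimulationConfig(
        n_participants=20,
        channels=list(DEFAULT_16),
        sfreq=64.0,
        epoch_window=(-0.2, 3.5),
        dc_window=(0.5, 3.0),
        noise_sd=NOISE_SD,
        dc_amplitude=2.0,
        factor_effect_gain=RECOVERY_GAIN if with_effect else 0.0,
        lambda_partition=0.5,
        lambda_onset=0.5,
        seed=seed,
    )


def recovery_analysis_config(seed: int, n_perm: int = 500) -> AnalysisConfig:
    """Matching pipeline settings (30 Hz band capped to the 64 Hz rate)."""
    return AnalysisConfig(filter_high=20.0, n_perm=n_perm, n_boot=500,
                          seed=seed)
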