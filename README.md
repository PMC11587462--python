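# patternglare

Analysis tools for sustained ("DC-shift") EEG responses to pattern-glare
stimuli — striped gratings presented continuously for several seconds, with a
clinically relevant *medium* spatial frequency (~3 cycles/degree) flanked by
*thin* and *thick* control gratings.  The package is aimed at EEG/ERP
researchers studying cortical hyper-excitability, habituation and
sensitisation: it simulates the full experimental design with known ground
truth, and analyses it (or equivalently structured real data) with
mass-univariate cluster-based permutation statistics.

## What it computes

**Pattern Glare Index (PGI).**  Hyper-excitation predicts a medium-stimulus
response more extreme than the control midpoint, so every analysis operates
on

    PGI = medium − (thick + thin) / 2

computed element-wise over participant × bin × channel × time.  If the brain
only tracked spatial frequency, the medium response would sit at the control
midpoint and the PGI would vanish.

**Dependent variables.**  Epochs (one per 3 s stimulus onset) are band-pass
filtered, average-referenced, baselined to −200–0 ms, thresholded at ±100 µV,
and averaged into four binned layouts: the collapsed average of onsets 2–8;
the three experimental blocks ("partitions", coarse time granularity); the
onset-pairs {2,3}, {4,5}, {6,7} (fine granularity); and the 3 × 3
partition-by-onset-pair grid.  Participants need ≥ 20% usable trials per
condition.

**Design regressors.**  Questionnaire scores and in-experiment discomfort
ratings are reduced to three varimax factors (visual stress, headache,
discomfort).  Habituation/sensitisation hypotheses are encoded as the factor
scores (shifted non-negative) tiled across time bins and weighted by an
exponential change pattern `exp(−λ·(k−1))` (decrease) or its reverse
(increase), then mean-centred; a three-way form multiplies an onset-pair
pattern with a partition pattern.  The per-factor interaction regressors are
Gram–Schmidt orthogonalised in the order visual stress → headache →
discomfort.

**Inference.**  Per channel × time sample the PGI is regressed on a single
regressor (OLS; the intercept regressor is a one-sample *t* test).  Samples
beyond the Student-*t* quantile at forming probability 0.025 per tail are
clustered under spatial adjacency + temporal succession; the cluster mass is
the summed *t*.  Family-wise error is controlled per tail at α = 0.05 by the
Monte-Carlo max-mass distribution — participant sign-flips for the intercept,
whole-participant regressor shuffles for covariates — with
p = (b + 1)/(m + 1) over 10 000 permutations by default (configurable
escalation to 25 000 for borderline effects).  Reported per cluster: p-value,
peak electrode (most member timepoints), peak time, r and both Cohen's *d*
conventions, temporal extent.

**Synthetic studies.**  The generator reproduces the design — 3 blocks × 6
trials per stimulus × 7–9 onsets, five-point discomfort ratings, a 7-measure
behavioral battery with block loading structure — and injects a posterior
DC shift for the medium stimulus whose amplitude follows
`dc + gain·s_p·exp(−λ_part·(j−1))·exp(+λ_onset·(i−1))` for discomfort score
`s_p`, partition `j`, onset-pair `i`, on top of AR(1), spatially correlated
noise.  Ground truth (factor scores, effect support, per-bin amplitudes) is
returned for recovery testing.

## Worked example

Simulate the benchmark study with an injected discomfort × partition-
habituation effect and run the discomfort-by-decrease analysis:

```python
from patternglare.presets import recovery_sim_config, recovery_analysis_config
from patternglare.workflow import run_pipeline
from patternglare.reporting import cluster_table

result = run_pipeline(
    recovery_sim_config(seed=500),          # injected effect, known truth
    recovery_analysis_config(seed=500),
    analyses=[("partitions", "twoway:discomfort:decrease")],
)
print(cluster_table(result.mua, p_cutoff=0.1).to_string(index=False))
```

which prints (abridged to the key columns):

```
                            regressor  tail  p_value electrode  peak_time_s  r_effect  d_regression  temporal_extent_s  significant
partitions|twoway:discomfort:decrease    -1 0.001996        A7     0.940625 -0.521875     -1.223591           2.421875         True
partitions|twoway:discomfort:decrease     1 0.009980       B16     2.550000  0.621401      1.586232           2.484375         True
```

The positive-tail cluster sits on the injected right-posterior support
(peak electrode B16) and spans essentially the whole 0.5–3.0 s analysis
window: the discomfort-weighted habituation pattern is recovered at
p ≈ 0.01.  The mirror-image negative cluster (peak A7) is the
average-reference counterpart of the same generator — re-referencing makes
any focal effect reappear with opposite sign on the remaining electrodes,
exactly as dipolar cluster pairs appear in real recordings.

The same pipeline is scriptable from a shell:

```bash
patternglare run-all --seed 7 -o pg_out          # simulate + analyse + report
patternglare simulate -c config.yaml -o work     # or stage by stage
patternglare preprocess -c config.yaml -o work
patternglare factors    -c config.yaml -o work
patternglare mua        -c config.yaml -o work
```

Delimited TSV tables (cluster table, t-maps, cluster masks, grand averages
with 5000-replicate percentile-bootstrap 95% CIs) are the canonical outputs;
figures are a rendering layer on top.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its relation to real EEG, all tunable parameters with units
and defaults, and the numerical design choices.
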