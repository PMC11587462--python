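# Methods

This note documents the models and procedures implemented in
`patternglare`, the assumptions behind them, the parameters that matter, and
the numerical choices made where the design was genuinely open.

## 1. The experimental design being modelled

A pattern-glare session presents horizontal square-wave gratings at three
spatial frequencies — thin and thick controls around a medium (~3 c/deg)
grating known to aggravate visually sensitive individuals — in three blocks
("partitions") of six trials per stimulus type.  Each trial is a train of
7–9 *onsets* of the same grating, each shown continuously for 3 s; the
participant rates discomfort on a 1–5 scale after every trial.  Because the
stimulus stays on, the EEG settles into a quasi-stationary state shifted
relative to the pre-stimulus baseline; we call the 0.5–3.0 s post-onset
stretch the **DC-shift period** and analyse it as such.

Hyper-excitation is operationalised through the **Pattern Glare Index**,
`PGI = medium − mean(thick, thin)`: any response component that merely
tracks spatial frequency places medium at the control midpoint and cancels.

## 2. Synthetic data generator

`synthetic.simulate_study` emulates this design with fully known truth.

* **Trial structure** — exactly the layout above; the number of onsets per
  trial is drawn from `{7: 0.4, 8: 0.4, 9: 0.2}` (nine onsets are the rare
  case).  One epoch per onset, −0.2 to 4.0 s around onset by default.
* **Signal** — only medium epochs carry signal: a constant (DC) amplitude on
  a raised-cosine posterior topography (default centre electrode B16, radius
  0.3 layout units) during the DC window,

      A(p, j, i) = dc_amplitude
                 + gain · s_p · exp(−λ_part (j−1)) · exp(+λ_onset (i−1)),

  with `s_p` the participant's true discomfort factor score, `j` the
  partition and `i` the onset-pair index (onsets {2,3}→1, {4,5}→2, {6,7}→3,
  {8,9}→4 by extrapolation; onset 1 uses index 1 and is excluded from every
  analysis anyway).  This encodes exponential habituation across the
  experiment and sensitisation across repetitions, amplified by discomfort.
  The reported *effect support* mask comprises channels at ≥ 10% of the peak
  topography weight; the raised-cosine tail below that carries negligible
  energy.
* **Noise** — stationary Gaussian, AR(1) along time (default coefficient 0.9
  at 128 Hz) with spatial covariance `exp(−d/ℓ)` over the electrode layout
  (default ℓ = 0.5 disc units), single-epoch SD 20 µV.  These are realistic
  scales for ongoing EEG; they are *choices*, not estimates from any
  dataset.  An optional artifact switch injects rectangular ±150 µV spikes
  to exercise the rejection stage, with a ledger of affected epochs.
* **Behavior** — six questionnaire measures are loading-matrix combinations
  of three latent factors (visual stress, headache, discomfort) plus
  independent noise (uniqueness SD 0.4), mapped to questionnaire-like native
  ranges; the seventh measure, the in-experiment **discomfort index**, is
  derived from the simulated per-trial ratings (latent Gaussian
  `2.5 + 0.8·s_p·[medium] + 0.5·ε`, rounded and clipped to 1–5), making it a
  state measure tied to the discomfort factor, as in the paradigm.
* **Determinism** — a single `default_rng(seed)` drives everything; equal
  configs give bit-identical output.

**What the generator does not emulate:** ocular/muscle artifacts (no ICA
stage is needed or provided — only an import hook), volume-conduction
physics beyond a smooth topography, non-stationary noise, onset/offset
transients (the injected effect is a clean step), and the idiosyncratic
covariance of real questionnaire batteries.  Passing recovery tests on this
generator therefore demonstrates correctness and calibration of the
*analysis machinery* under the design's statistical structure, not
performance on any particular real dataset.

* **Sampling rate** — the generator defaults to 128 Hz.  The analyses live
  entirely below 30 Hz, so this preserves the relevant signal content while
  keeping a full default study (38 participants, 32 channels, ~16 000
  epochs) comfortably in memory; the `decimate` stage supports
  integer-factor reduction (e.g. 2048 → 512 Hz) for data recorded at higher
  rates.

## 3. Preprocessing

Order: band-pass filter → (optional) decimate → average reference →
baseline (−200–0 ms) → ±100 µV rejection → 20% inclusion rule → binning.

* **Filtering.**  `bandpass_filter` uses a Hann-windowed linear-phase FIR
  (length ≈ 3.3·fs / 7.5 Hz, odd), applied zero-phase with reflection
  padding.  Band-pass/high-pass designs are forced to an *exact* DC null by
  subtracting a Hann-shaped component scaled to the taps' sum — the Hann
  shape concentrates the correction's spectrum at 0 Hz, so the passband is
  untouched (a flat correction would spray Dirichlet-kernel ripple across
  it).  **Default pipeline choice:** epoched synthetic data are low-passed
  at 30 Hz only.  A high-pass whose kernel is much shorter than the 2.5 s
  sustained plateau has zero-sum taps and would annihilate exactly the DC
  shift under study; sub-Hz high-passing belongs on continuous recordings
  before epoching, and the per-epoch baseline correction already removes
  slow offsets here.  The high-pass remains available for continuous or
  long-window use.
* **Rejection and inclusion.**  Any epoch with |value| > 100 µV at any
  sample is dropped (logged with participant, trial, onset, worst channel
  and extremum).  A participant is retained iff usable/total ≥ 20% in
  *every* condition; the boundary is inclusive.
* **Binning.**  Usable epochs are averaged with equal weight into the cells
  of the four schemes.  Onset 1 (surprise) and onset 9 (rare) never
  contribute; onset 8 enters the 2–8 and partition schemes but no
  onset-pair bin.  Cells with zero usable epochs are flagged missing;
  participants with a missing required cell are dropped from that scheme's
  analysis only, so different analyses may run on different n — as happens
  in practice.

## 4. Factor analysis

The seven measures are z-scored (sample SD) and reduced by
**principal-component factoring**: loadings are the top-3 eigenvectors of
the correlation matrix scaled by root eigenvalues, varimax-rotated
(iteration from the identity, deterministic).  ML extraction was rejected
because a factor carried essentially by a single indicator — the discomfort
index — is unidentifiable under an ML uniqueness model (the
loading/uniqueness likelihood is flat), whereas the principal-component
solution keeps it well-defined; PC factoring is also common practice for
questionnaire batteries of this size.  Scores use the regression (Thomson)
method `S = Z R⁺ Λ` (pseudo-inverse, so noise-free rank-deficient batteries
work).  Factors are labelled by the measure block with the largest mean
absolute loading via greedy best-match; genuinely tied claims raise an
error.  The number of factors is fixed at 3 by configuration — the scree
decision is treated as an analyst's judgment, not automated — and the full
eigenvalue sequence is returned for inspection.

## 5. Design regressors

All regressors are one value per (bin, participant) row, rows ordered
partition-major, then onset-pair, then participant, matching the flattened
binned data exactly (checked structurally before any fit).

* **Intercept** — all ones; one-sample inference is implemented directly
  with sign-flip permutation.  The equivalent construction that duplicates
  the data with zeros and runs a two-sample test produces the identical t
  statistic (asserted in tests); the direct form is used because the
  workaround exists only as a toolbox limitation elsewhere.
* **Two-way interaction** — shift factor scores non-negative (subtract the
  minimum), tile across the 3 bins, multiply bin k's copy by
  `exp(−λ(k−1))` (decrease) or the reversed sequence (increase), mean-
  centre.  λ defaults to 1 per bin step and is configurable: the
  permutation test is invariant to positive affine rescaling of the
  regressor, so λ fixes only the hypothesised *shape* of change.
* **Three-way interaction** — per participant the 9 cell values are the
  outer product of the onset-pair and partition weight vectors scaled by
  the shifted score, then mean-centred over all 9·n rows.
* **Orthogonalisation** — the three per-factor interaction regressors are
  Gram–Schmidt processed in the order visual stress → headache → discomfort
  (the scree-strength order), projection removal only, first vector
  unchanged, outputs re-centred.  Unorthogonalised variants are a config
  switch.  If all factor scores are equal the regressor degrades to the
  pure change pattern; this warns rather than fails because the
  permutation null remains valid.

## 6. Cluster-based permutation inference

* **Statistic map** — per channel × time sample, OLS of the PGI on
  `[1, x]`; t = slope/SE with df = n−2 (df = n−1, one-sample, for the
  intercept).  Degenerate zero-residual fits are capped at |t| = 10⁶ and
  flagged; the cap keeps cluster masses finite without changing any
  ordering.
* **Clustering** — suprathreshold samples (per-tail forming probability
  0.025 mapped through the Student-t quantile at the model df) are grouped
  into connected components under channel adjacency (edge iff layout
  distance ≤ 0.45 by default) at the same timepoint plus temporal
  succession at the same channel.  Cluster mass = Σ member t (the "maxsum"
  convention).  The implementation reduces each suprathreshold set to a
  sparse graph and runs connected components; tests cross-check membership
  and masses against an independent flood-fill and against an established
  external cluster engine.
* **Permutation null** — per tail, the distribution of the maximum |mass|.
  Exchangeability: the intercept flips the sign of each participant's
  entire PGI (all bins/channels/times); covariate designs permute whole
  participants' regressor row-blocks, because factor scores are a
  between-participant property and bins must travel with their participant.
  When 2^n sign assignments fit within the requested permutation count the
  engine enumerates them all, making the p-value exact.
* **P-values** — `p = (b + 1)/(m + 1)`, never exactly zero, with a 10⁻⁹
  relative tie tolerance so the observed assignment's own twin in an
  exhaustive null is counted despite round-off.  Clusters are tested
  against their own tail's null at α = 0.05 per tail; a borderline-p
  escalation to 25 000 permutations is available behind a config flag.
* **Effect sizes** — at the cluster's peak-|t| sample:
  `r = sign(t)·√(t²/(t²+df))`, one-sample `d = t/√n`, regression
  `d = 2t/√df`.  Both d conventions are emitted and labelled because
  neither is canonical for this statistic.  The peak electrode is the
  channel with the most member timepoints (ties: larger Σ|t|, then channel
  name) — the rule used for grand-average plotting.

## 7. Reporting

Median splits (for visualisation only) send scores strictly above the
median to the high group; scores at the median go low — a fixed,
documented tie rule.  Grand-average confidence bands use a percentile
bootstrap: participants are resampled with replacement, one resample per
iteration driving *all* conditions so cross-condition correlation (hence
PGI bands) is preserved, 5000 iterations, 2.5/97.5 percentiles per
timepoint.  Delimited TSVs (cluster table, t-maps, masks, grand averages
with bands) are the canonical, byte-deterministic outputs; matplotlib
figures are a thin rendering layer excluded from numeric guarantees.

## 8. Benchmark problem sizes

The validation computations (test suite and `scripts/acceptance.py`) run
the full design at reduced scale, chosen once: 20 participants, a
16-channel posterior-weighted subset of the 32-electrode layout, 64 Hz, 10
µV noise.  Calibration uses 200 pure-noise studies at 500 permutations;
the injected-effect benchmark sets the discomfort gain to 3× the noise SD
of the analysed per-cell averages (≈ 40 epochs per partition cell, so gain
≈ 4.8 µV per unit score) — the scale at which an effect is strong at the
level of the dependent variable actually tested while the data retain
realistic residual structure.  Bootstrap coverage uses 500 replications of
30 Gaussian participants.  These sizes make a single analysis take seconds
and the full validation a few minutes on one CPU.

## 9. Known limitations

* The exponential change patterns assume a fixed, known shape; only the
  rank structure is identified by the permutation test, and λ is not
  estimated from data.
* Average referencing necessarily mirrors any focal effect onto the
  remaining electrodes with opposite sign; interpretation of cluster tails
  must account for such dipolar pairs (the synthetic benchmark reproduces
  this).
* Principal-component factoring slightly inflates loadings relative to a
  uniqueness-modelling extraction; with one- and two-indicator blocks this
  is the price of identifiability.
* The engine targets epoched, binned designs of this family; continuous-
  data preprocessing (sub-Hz filtering, ICA) is expected to happen
  upstream, with only an import hook provided.
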