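# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `esrstack`, and what its synthetic benchmarks do and do not
demonstrate.

## Synthetic sedimentation curves

A subject's normalized column height is modelled as a rescaled logistic,

    h(t) = 1 − (1 − esr_final) · (F(t) − F(0)) / (F(60) − F(0)),
    F(t) = 1 / (1 + exp(−rate · (t − t_mid))),

on the fixed grid t = 0, 0.5, …, 60 min (121 points). The form was chosen
for three reasons: it reproduces the characteristic lag / fast-sedimentation
/ packing sequence of real columns; the rescaling pins h(0) = 1 and
h(60) = esr_final exactly, which the normalization of a real measurement
implies; and the sedimentation velocity −dh/dt peaks exactly at `t_mid`, so
the velocity-peak time is a directly controllable property.

Default priors (uniform, independent):

| parameter | normal group | periodontitis-like group | why |
|---|---|---|---|
| esr_final | U(0.35, 0.86) | U(0.35, 0.55) | matches the documented endpoint range at 35% hematocrit; the patient group sediments further |
| t_mid (min) | U(10, 20) | U(6, 16) | velocity peaks of real columns fall in the 10–20 min window; inflammation accelerates the aggregation phase by ~4 min |
| rate (1/min) | U(0.18, 0.40) | same | gives clearly sigmoidal curves whose fast phase lasts 5–20 min |
| noise sd | 0.004 | same | small relative to signal (h spans ~0.14–0.65), keeps interface detection solvable |

Noise is i.i.d. Gaussian added to the noiseless curve; an optional
cumulative-minimum projection restores monotonicity but is **off** by
default, since measured curves are modelled as-is rather than
post-processed. All randomness flows from one integer seed through spawned
per-curve sub-seeds (recorded on each curve), so cohorts are bitwise
reproducible.

Only the endpoint range and qualitative velocity behaviour of real cohorts
are published; the priors are therefore stipulated study conditions, not
estimates. Real curves have subject-correlated noise, meniscus artifacts and
slight non-monotonicity near packing that the generator does not emulate, so
passing benchmarks demonstrate correct mechanics and orderings, not clinical
error levels.

## Measurement pipeline

Frames are assumed pre-cropped to the column region, 8-bit grayscale, row 0
at the top (plasma side).

- **Otsu threshold**: exact maximizer of between-class variance over all 256
  candidate thresholds (vectorized cumulative sums); ties break to the
  smallest threshold. Pixels above threshold map to 1 (plasma).
- **Interface**: the single changepoint c minimizing the summed squared
  deviation of the two segments from their own means, computed exactly for
  every cut via prefix sums; ties break to the smallest c. h = 1 − c/n_rows.
  This is the classical single-changepoint squared-error statistic; no
  multi-changepoint search and no penalty term are needed for a two-phase
  column.
- **Degenerate frames**: a constant frame (the t = 0 column is legitimately
  all-dark) maps to h = 1 if its gray level lies at or below a stack-global
  Otsu threshold and h = 0 otherwise, instead of failing the stack. The same
  rule is applied when Otsu's two classes differ by less than 20 gray levels
  — in that regime the threshold is splitting pixel noise, not an interface.
  The constant 20 is conservative: renders use erythrocyte/plasma levels
  60/200, so genuine interfaces produce class contrasts near 140.
- **Polarity**: plasma is asserted to be the brighter class on top; if the
  upper segment is darker the binarization polarity is flagged with a
  warning. The changepoint location itself is invariant to polarity.
- **Velocity**: V_E = −dH/dt by central differences (one-sided at the ends),
  optionally scaled to mm/min by the 53-mm column height.

No smoothing is applied to extracted curves before modelling.

## Base forecasters

The three architectures are implemented directly in numpy: the networks are
tiny (≤ 15 hidden units, ≤ 41-step sequences), so explicit forward passes
and hand-written backpropagation(-through-time) are fast, dependency-free
and — more importantly here — testable against independent matrix-arithmetic
oracles and finite differences. Gate weights are stored fused (one matrix
per input/recurrent path) for speed; per-gate views under the standard names
(W_i1, W_z2, …) are exposed for the JSON weight dump and the oracle tests.

Training protocol (all configurable in `TrainConfig`):

| setting | default | note |
|---|---|---|
| optimizer | Adam (β₁ = 0.9, β₂ = 0.999) | |
| learning rate | 1e-2 · 0.96^(step/100) | continuous exponential decay; initial rate and decay constants are package choices |
| loss | MSE | |
| batch size | 32, reshuffled per epoch | |
| epochs | ≤ 300, early stop patience 15 on val loss | best-validation weights restored (standard practice) |
| MLP hidden activation φ | rectifier | configurable; tanh/identity available |
| initialization | Glorot-uniform per gate, zero biases | driven by the config seed |

Inputs are the raw h values in (0, 1] — normalization is inherent to
H_E/H_T — and targets are unscaled. The MLP flattens the window (it cannot
exploit temporal order); the recurrent models consume it as a univariate
sequence whose final hidden state feeds one linear output neuron. Window
lengths are restricted to the standard sweep set {5, 7.5, …, 20} min unless
explicitly overridden. Training is deterministic for a fixed seed
(single-threaded numpy).

## Stacking ensemble

- **Stage one**: N_B bases of one architecture, each trained on an
  independent bootstrap resample (size = training-set size, drawn with
  replacement) with its own recorded seed.
- **Stage two**: the meta model is fitted on the bases' forecasts for the
  **validation split**, not the training split. Fitting on training
  predictions would let overfit bases dominate the combiner; the validation
  forecasts are the honest estimate of each base's out-of-sample behaviour.
- **Intercepts**: both LASSO and PLSR include an intercept via centering.
  ESR forecasts live near 0.3–0.9, so a no-intercept fit would conflate
  scale with bias.
- **LASSO**: objective ‖y − Zβ‖² + λ‖β‖₁; the inner solve is
  scikit-learn's coordinate descent with the penalty rescaled accordingly.
  The λ grid holds 50 log-spaced values from λ_max (the smallest penalty
  zeroing all slopes) down four decades. λ is chosen by fivefold CV on
  squared error (no one-SE rule); folds are contiguous blocks after one
  seeded shuffle, and the fold seed is recorded.
- **PLSR**: scikit-learn's NIPALS implementation (`scale=False`; columns are
  forecasts of the same quantity and share units, so variance scaling would
  only amplify the noisiest base). J ranges over 1..rank(Z), chosen by the
  same CV scheme; with J = rank the predictions coincide with least squares,
  which the tests exploit as an oracle.
- Every ensemble records seeds, bootstrap index sets and the CV curve in a
  JSON manifest.

## Evaluation protocol

The cohort is split once per experiment by seeded shuffle into
train/validation/test at the 194/50/60 reference proportions (scaled for
smaller cohorts). D repetitions rerun all fitting with fresh sub-seeds —
weight initialization, batch order and bootstrap draws vary; the split does
not. Within one repetition, ensemble entries sharing a base family and N_B
reuse the same trained bases, so meta-models are compared on identical first
stages. MAPE is reported in percent, RMSE in h-ratio units; summaries are
means ± SD (ddof = 1) over repetitions. Sweeps re-run this protocol over
window lengths {5, …, 20} min or ensemble sizes 3–10.

## Statistical comparison

- Friedman ranks are ascending in error (rank 1 = best, average on ties);
  the default p-value uses the classical chi-square approximation with tie
  correction (cross-checked against scipy). Two alternatives are available:
  the Iman–Davenport F variant, and a within-row permutation p-value
  (exhaustive when the null space is small, seeded Monte Carlo otherwise) —
  the permutation method is the appropriate choice at very small D, where
  the chi-square approximation is off by severalfold.
- The Nemenyi q_α table embeds studentized-range values (infinite df) / √2
  for k = 2..15 at α = 0.05 and 0.10; the headline 11-model, 30-repetition
  comparison gives CD = 3.219 · √(132/180) ≈ 2.76. The 11-model roster is
  MLP, LSTM, GRU plus {LSTM, GRU} × {Mean, Median, LASSO, PLSR}.
- Grouping bars for critical-difference diagrams are maximal runs of
  rank-adjacent models whose mean-rank spread is below CD.
- Bland–Altman differences are predicted − actual; limits of agreement are
  bias ± 1.96 · SD (ddof = 1).

## Pipeline

`run_pipeline` chains simulate → extract → evaluate → compare → report into
a run directory with a manifest (config, per-stage seeds, file checksums).
Repeated training and its evaluation are one protocol, so they form a single
`evaluate` stage rather than separate train/evaluate stages. The extract
stage either passes ground-truth curves through (default) or renders image
stacks and re-measures them, exercising the imaging pipeline end-to-end.
Input windows shorter than 5 min are rejected without an explicit override,
since forecasts from such windows are known to be unusable. Stage seeds are
derived from the master seed, so two runs with the same seed produce
byte-identical tables.

## Problem sizes used by the test and acceptance suites

Benchmarks in this repository run at deliberately reduced scale, chosen as
the smallest sizes at which the qualitative orderings are stable: trend
checks use a 150-subject cohort with medians over 10 seeds; the repeated
evaluation in `scripts/acceptance.py` uses D = 5 repetitions of the full
11-model roster; the end-to-end determinism check uses 60 subjects and
D = 3. The full-scale operating point (304 subjects, D = 30, N_B = 8,
L = 15 min) is the default of `RunConfig`.

## Known limitations

- Absolute error levels on the synthetic cohorts are several times larger
  than what dense, low-noise clinical curves would give: the generator's
  independent uniform priors make the endpoint genuinely hard to pin down
  from 15 minutes when the velocity peak falls late. Model *orderings*
  (recurrent > MLP; regularized combiners > central-tendency combiners;
  longer windows > shorter) are the meaningful benchmark output.
- The patient group is a stylized fast-sedimenting population, not a
  clinical periodontitis cohort; Bland–Altman numbers on it characterize the
  pipeline, not the disease.
- The changepoint detector assumes exactly one interface; columns with
  transient stratification would need a multi-changepoint extension.
- No GPU support and no minibatch parallelism — by design, for exact
  reproducibility on one CPU.
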