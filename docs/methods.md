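# Methods

## Data model

A peak table is a metabolite × sample matrix of non-negative peak areas
with per-metabolite annotations (name, monoisotopic mass in Da,
retention time in minutes).  Blank or NA cells are *missing* and are
kept distinct from literal zeros throughout: peak-processing pipelines
conflate non-detection with absence, so each downstream operation
decides explicitly how to treat missing values rather than silently
coercing them.

The sample sheet is the ordering authority.  Each sample belongs to a
subject, a time-point label and a phase group under a fixed mapping —
PRE = {P1, P2}, POST1 = {PT1, PT2, PT3}, POST2 = {PT4..PT8} — with a
0-based collection index giving chronological order within subject.
File column order is never used for ordering, since acquisition order
in LC-MS batches is typically randomised.

## Normalisation strategies

With `x[m, s]` the raw area of metabolite `m` in sample `s`:

- **area_percent**: `100 · x[m, s] / Σ_{s' ∈ subject(s)} x[m, s']`.
  Requires at least two samples per subject (a single-sample "sum"
  would force the output to a constant 100 and destroy all time
  structure, so it is an error).  Per-(metabolite, subject) sums are
  retained in the output's parameter record.  Metabolites whose
  within-subject sum is zero become missing for that subject and are
  reported in a warning.  The `missing_policy` for the sums defaults to
  `as_zero` (a missing peak contributes nothing to the total, the
  convention when summing peak-area tables); `propagate` is available
  and poisons the whole (metabolite, subject) block instead.
- **ms_creatinine**: `x[m, s] / x[creatinine, s]`.  The creatinine row
  is located by annotation-name match ("creatinine", case-insensitive);
  amongst several candidates the mass closest to the neutral
  monoisotopic mass 113.0589 Da arbitrates, preferring a 5 ppm window.
  A name match alone is accepted because peak tables frequently carry
  rounded or adduct-shifted masses.  The creatinine row itself becomes
  identically 1 and is retained so all strategies keep the same shape.
- **pooled_ms_creatinine**: division by one positive scalar per subject
  (e.g. the creatinine response of a subject-specific pooled sample).
  When no scalars are supplied, the strategy panel derives them as each
  subject's mean MS creatinine response, a documented stand-in for a
  pooled-sample measurement.
- **assay_creatinine**: division by a per-sample spectrophotometric
  creatinine concentration; positivity is enforced.

No log transform is applied by default anywhere — ratios and paired
t-tests operate on the percentage scale; a `log10_transform` helper
exists for exploration.

Algebraic properties (all tested): area% is exactly invariant under any
positive per-(metabolite, subject) rescaling of the input and its rows
sum to 100 per subject; per-sample creatinine division is exactly
invariant under per-sample dilution (with the assay variant invariant
when the assay value tracks the dilution); the per-subject constant
divisor of the pooled variant preserves within-subject ratios.  None of
the creatinine strategies is invariant under block rescaling, and area%
is not invariant under per-sample rescaling — each strategy removes a
different nuisance.

## Stability diagnostics

RSD = 100 · s/x̄ with `s` the sample (n−1) standard deviation, the QC
convention.  By default RSD is computed on the raw scale across all
samples pooled; a per-subject scope exists.  Records with fewer than
two usable values or a non-positive mean are flagged rather than
dropped, so report row counts are conserved.  Stability reports bin
records into RSD bands at user thresholds; flagged records get their
own band so the counts always partition the records.

## PCA, R2X and Q2

Matrices are autoscaled per metabolite (mean-centred, unit variance,
n−1 SD); zero-variance columns are dropped with a warning.  Components
are extracted by NIPALS: initialise the score with the residual column
of largest variance (ties → lowest index), alternate loading and score
regressions over present elements only, normalise the loading, stop
when the score vector changes by less than `tol` (default 1e-9,
`max_iter` 500), deflate, repeat.  The sign convention makes each
loading's largest-magnitude element positive.  R2X per component is the
drop in residual sum of squares over the total.

When the matrix contains missing elements, the sequential solution is
refined by expectation-maximisation: missing elements are imputed from
the current rank-A reconstruction (starting from the column mean, i.e.
zero after centring) and the model is refitted until the imputations
stabilise.  Sequential present-element regressions are biased under
missingness, and on unstructured data they can converge to degenerate
loadings concentrated on sparsely observed variables with exploding
scores; iterated imputation converges stably to the joint least-squares
fit of the present elements.  Complete matrices take the plain NIPALS
path, which agrees with an SVD eigendecomposition to 1e-6 (tested on
random matrices up to 30 × 100).

Cross-validated Q2 deletes matrix *elements*, not rows: element (i, j)
belongs to fold `(i + j) mod k` (k = 7 by default) with fold labels
shuffled by the seed, so every row and column stays represented in each
training split; row-wise deletion on 30-sample unit-variance data is
unstable.  If striping ever leaves a fold with an empty training row or
column, folds are re-assigned at random with a warning.  With
`PRESS_a` the held-out squared error after `a` components (cumulative
reconstruction) and `RSS_a` the full-data residual SS (`RSS_0` = total
SS):

```
Q2_a     = 1 − PRESS_a / RSS_{a−1}
Q2_cum(A) = 1 − Π_{a≤A} PRESS_a / RSS_{a−1}
```

Q2 can be far below zero on structure-free data: an unregularised
rank-A fit of pure noise predicts held-out elements worse than the mean
does, occasionally much worse.  That is the behaviour the |R2X − Q2|
gap criterion exploits — models that fit variance they cannot predict
are penalised.

The strategy panel fits one 2-component model per normalisation
strategy on the identical sample ordering (by subject, then collection
index) and the identical fold pattern, annotates scores with subject
and phase, and reports (strategy, R2X_cum, Q2_cum, |R2X_cum − Q2_cum|)
sorted by gap.  Two components are used because the comparison is about
2-D score structure; the general API allows more.

## Reference-point comparisons

Fold ratios are ratios of subject means (reference mean / comparator
mean), not means of per-subject ratios: with as few as three subjects a
single near-zero comparator value would otherwise explode the
statistic.  A zero comparator mean yields an `infinite` flag, not an
exception.  Paired t-tests use per-subject differences d_k =
reference_k − comparator_k, t = d̄/(s_d/√n), df = n−1, two-sided p.
Degenerate spreads are flagged (s_d = 0 with d̄ ≠ 0 → p undefined;
all-zero differences → t = 0, p = 1).  The default comparison set is
PT1 against P1, P2, PT2, PT4, PT5 and PT7.  No multiple-testing
correction is applied by default, mirroring the convention of reporting
raw paired-t p-values from small-n exploratory designs; a
Benjamini–Hochberg q-value column is available.

## The synthetic generator

Observed areas decompose exactly as
`x[m, s] = d_s · b[m, subj(s)] · f_m(t_s) · ε[m, s]`, all factors
log-normal, so the emitted table can be re-composed bit-for-bit from
the stored truth.  Defaults emulate the pilot design: 3 subjects, 10
collections at hours {0, 3, 6, 9, 13, 24, 28, 30, 33, 37} (day 1 at
08:00 = hour 0), exercise at hour 4; 80 metabolites split 40 stable /
20 spike / 10 diurnal / 10 erratic plus a creatinine row.

- Spikes: `f = 1 + A·exp(−(t − t_ex)/τ)` after the exercise hour, A
  log-uniform in [2, 100], τ uniform in [2, 10] h — exercise responses
  peaking at the first post-exercise void.  Amplitudes are capped at
  100-fold; larger printed ratios occur in real data but are
  ratio-scale-unstable and would dominate every summary.
- Diurnal: `f = 1 + a·sin(2π(t + φ)/24)`, a ∈ [0.2, 0.8], random phase.
- Erratic: independent log-normal draws per time point (σ = 0.5),
  emulating diet-driven xenobiotics.
- Noise scales: dilution σ_d = 0.4, subject × metabolite baseline
  σ_b = 0.6, measurement noise σ_ε = 0.1.  These are assumptions chosen
  to span the observed spread of raw-scale metabolite RSDs in serial
  urine collections (roughly 16%–200%); the true variance components of
  any given study are unknowable without its raw data.
- Creatinine: a stable metabolite (mass 113.050, RT 10.1 min) whose own
  noise σ is solved so that its raw-scale RSD across samples (dilution
  included) matches a configured target (default 16.3%); when dilution
  alone already exceeds the target the σ clamps to a small floor.  Its
  baseline is held constant across subjects so the target is meaningful.
  The assay table is `d_s · creatinine baseline · exp(N(0, σ_assay))`
  with σ_assay defaulting to 0.5, reflecting the far poorer precision
  of plate-reader creatinine assays relative to MS; setting σ_assay = 0
  makes the assay exactly proportional to the true dilution.
- `null_dataset` makes every metabolite stable.  Its `additive` mode
  replaces dilution and multiplicative noise with relative additive
  Gaussian noise (d = 1, ε = 1 + N(0, σ_ε)) so that paired t-tests on
  the area-percentage scale meet their normality assumption; this is
  the configuration used for type-I-error calibration.

Truth recovery is scored two ways: the Pearson correlation between each
(metabolite, subject) normalised profile and the true temporal profile
(flat truths flagged), and the same correlation computed across all
subjects' samples jointly.  The across-subject score is the
discriminating one: a per-subject constant divisor (pooled creatinine)
leaves within-subject profiles untouched and ties area% per subject,
but only area% cancels the subject × metabolite baseline and aligns
profiles *across* subjects.  Spike metabolites additionally get the
relative error of their estimated vs true PT1/P1 fold.

What the generator does not emulate: m/z-level artefacts (adducts,
isotopes, RT drift), batch effects, censoring of low-intensity peaks
(missingness is optional and at random), and within-class correlation
beyond the shared temporal profile.  Passing tests therefore
demonstrate the algebra, the statistics and the regime logic of the
strategies, not performance on any particular real cohort.

## Regime separation

The generator makes the strategy comparison falsifiable in both
directions, asserted over 20 seeds each:

- baseline-dominated regime (σ_b = 1.5 ≫ σ_d = 0.1, σ_ε = 0.05):
  area% attains both the highest mean across-subject truth-profile
  correlation and the smallest |R2X − Q2| gap of the four strategies;
- dilution-dominated regime (σ_d = 0.8 ≫ σ_b = 0.05, assay exactly
  proportional to dilution): assay creatinine attains the highest mean
  correlation.

## Pipeline

`urinorm run` executes read/simulate → normalise (all requested
strategies) → RSD report → strategy panel → PT1-referenced comparison
table, writing TSV outputs plus a JSON manifest with SHA-256 checksums
of every file.  Runs are single-process and deterministic: one global
seed fans out to stage seeds by fixed offsets, so identical config +
seed gives identical checksums.  A failing stage aborts with the stage
name and removes partial outputs.  Config files are YAML, strict-keyed,
and validation collects all errors before reporting.

## Problem sizes

The test suite and the acceptance script use the defaults above (30
samples × ~80 metabolites) for panel work, 2000 metabolites for
type-I calibration, matrices up to 30 × 100 for the PCA oracle checks,
and 10–20 seeds for the stochastic assertions; these sizes give
Monte-Carlo margins comfortably inside the asserted tolerances.
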