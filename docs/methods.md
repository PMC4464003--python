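# Methods

This note records the statistical model behind `biopanel`, the defaults
and why they were chosen, the numerical decisions, and what the
synthetic-data experiments do and do not demonstrate.

## 1. Data model and preprocessing

A cohort is a subjects × features table with a diagnostic label per
subject (three classes — HC, MCI, AD — contrasted pairwise), continuous
measurements and binary {0,1} clinical flags, and missing cells.

**z-standardization.** Every feature is replaced by
z_ij = (x_ij − μ_j)/σ_j where μ_j and σ_j are the mean and *sample* SD
(n−1 denominator) over all non-missing values of the **whole loaded
population** — all classes, before any per-contrast restriction.  The
n−1 denominator matches the default of mainstream statistics
environments; the whole-population convention means a feature's z-scale
is shared across the three pairwise analyses.  Binary flags are
standardized identically (they are just variables); a constant column
raises an error naming it, since its z-score is undefined.
Standardization happens *before* the per-contrast missingness filter —
the ordering is a package choice; the two operations commute on the
surviving features up to nothing at all, because μ_j and σ_j never
depend on the contrast.

**Missingness.** Within one contrast, a feature is dropped when its
missing fraction strictly exceeds 0.20 in *either* class ("more than
20%" — exact ties are retained).  Afterwards, every fit, CV fold and
IDI comparison uses the complete cases of exactly the features
involved.  There is no imputation anywhere; missingness is handled only
by these two rules.

## 2. GA wrapper search

Each of `n_ga_models` (default 1,000) independent runs evolves a
population of 50 chromosomes — sets of exactly 5 distinct features —
for `ga_generations` (default 300) generations.  Fitness is the
stratified k-fold cross-validated accuracy (probability threshold 0.5)
of the logistic model on the chromosome's complete-case subjects;
k = 4 for the HC-AD contrast and 3 for HC-MCI and MCI-AD.  GA internals
left open by the methodology are fixed as standard wrapper-GA practice
and exposed in `AnalysisSpec`: tournament selection of size 2, elitism
preserving the single best, uniform crossover with repair to distinct
genes, and per-gene mutation probability 0.02 to a uniformly random
unused feature.  Run r draws everything (initial population, fold
assignment, selection, crossover, mutation) from one generator seeded
`rng_seed + r`, so a batch is exactly reproducible and frequencies obey
the conservation law Σcounts = n_runs × 5.

**Fitness kernel.** A full search fits millions of small logistic
models, so CV fitness is computed by a compiled Newton/IRLS kernel
(numba) with a hand-coded Cholesky solve.  The kernel caps Newton at 5
iterations and stops early when the largest step falls below 1e-3:
only the induced classification is consumed, and the 0.5-threshold
decision boundary is stable well before the score vanishes.  Separation
inside a fold is harmless for the same reason (the truncated
coefficients still classify the training data perfectly).  The test
suite checks the kernel against the reference IRLS fitter on
well-conditioned folds.  Degenerate folds (one-class training part) are
skipped and accuracy pooled over the valid folds; a chromosome with no
valid fold scores 0.

**A caveat on all-noise frequency nulls.**  Because all runs share one
dataset, features with chance sample associations recur across runs;
final-model frequencies under pure noise are therefore *over-dispersed*
relative to a uniform multinomial, and only relative dominance (signal
frequency rising with effect size, planted features out-ranking noise)
is a sound expectation.  The tests assert exactly that.

## 3. Ranking, merging, forward selection, backward elimination

**Merging.** Features are visited in descending raw frequency (ties:
higher mean CV fitness, then name).  A visited feature absorbs the
frequency of every not-yet-absorbed lower-ranked feature with
|Pearson ρ| > 0.8 at p < 0.05 (ρ on the pairwise complete observations
of the selection population; p from the t transform
t = ρ√((n−2)/(1−ρ²)), two-sided; pairs with < 3 complete observations
are skipped with a warning).  The methodology states the rule per pair
without an order; the descending greedy pass is deterministic, conserves
total frequency exactly, and transfers counts in the stated direction
(most frequent absorbs).

**IDI.**  For nested ("old") and extended ("new") models scored on the
same subjects, with dp_i = p_new,i − p_old,i:

IDI = mean(dp | cases) − mean(dp | controls),
SE  = √(s²_cases/n_cases + s²_controls/n_controls),  z = IDI/SE,

with s the within-group sample SD of dp.  Probabilities entering the
IDI are **out-of-fold**: each subject is scored by the model fit on the
other k−1 folds, with one shared stratified fold assignment per
comparison so the nested and extended predictions are paired.  Both
models are evaluated on the complete cases of the union of their
features.

**Sidedness (a deliberate design choice).**  The reported p-value is
one-sided in the improvement direction, p = P(Z ≥ z).  With
cross-validated probabilities the null z is *negatively* drifted — the
extended model pays a CV penalty for its extra coefficient — so a
two-sided test rejects mostly on the negative tail, which signals harm,
not improvement, and no selection step ever acts on it; its empirical
size under a null added feature is ~0.09–0.12 at k = 3–4 instead of
0.05.  The one-sided test matches the directional question the gate
actually asks and is empirically calibrated (size 0.050 at k = 3 and
0.052 at k = 4 over 1,000 simulated 100-vs-100 cohorts; the acceptance
suite re-verifies this).  The two-sided companion is still exposed as
`IdiResult.p_two_sided`.

**Forward selection** walks the merged ranking (capped at the top 50 to
bound runtime; panels beyond the top ranks never survive the gate in
practice) from the intercept-only model, admitting a candidate iff its
IDI is positive with p < 0.05.  Failing candidates are skipped and the
walk continues — final panels observed in practice mix ranks, which a
stop-at-first-failure rule could not produce (that stricter rule is
available as a flag).  The classical maximum-fitness-over-nested-models
rule is *not* applied; the IDI gate alone is the operative criterion.
At a 5% gate, ~1 false admission per ~20 null candidates is expected —
**backward elimination** is what removes them: each cycle recomputes,
for every feature f in the model, the IDI of the model versus the model
without f (on the model's complete cases, shared folds, a fresh seeded
fold draw distinct from the FS stage), removes the feature with the
smallest z if its p > 0.05, refits, and stops when every remaining
contribution is significant.

## 4. Validation

The most-incomplete 25% of the contrast's subjects (by missing fraction
across the filtered panel; deterministic tie-break by subject id) sit
out of feature selection — emulating a study whose selection cohort
required broad data availability — and are re-examined once the final
panel is fixed: those complete on the panel's features form the APIS
pool.  A seeded simple random sample of m APIS subjects (optionally
class-stratified) joins the selection population as the calibration
set, with m solving |selection| + m = ratio·(|APIS| − m) for the 4:1
calibration:test ratio (rounded, clamped with a warning when
unreachable); the remaining APIS subjects are the blind test set.

Coefficients are refit on the calibration set (no reselection); sign
flips against the selection-time fit are logged.  The *fixed*
calibrated model is then evaluated with class-stratified bootstrap
resampling (default 1,000 resamples; the model is deliberately not
refit per resample — a refit variant exists behind a flag), reporting
each metric's full-sample point value, bootstrap mean and 2.5/97.5
percentile interval.  Stratification is a package choice the
methodology is silent on: sensitivity and specificity are per-class
ratios and unstratified resampling can empty a class.  A degenerate
resample is redrawn at most 10 times.

The chance-performance experiment draws `n_random_models` (default
1,000) feature sets of the final panel's size uniformly without
replacement from the filtered feature pool, fits each on the
calibration set and bootstrap-evaluates it identically; the probability
of a chance panel matching the proposed one is the proportion of random
panels outperforming it, computed separately for bootstrap-mean
accuracy and AUC, with 2.5/97.5 percentile bands and a per-model
density export.

## 5. Core estimators

* Logistic regression: hand-written IRLS on [1 | X], convergence when
  max |score| < 1e-8 or relative deviance change < 1e-10 (cap 100
  iterations); rank-deficient designs raise; separation is detected by
  perfect prediction at a saturated clipped linear predictor and
  flagged non-converged with a warning.  Wald z and two-sided p per
  coefficient from the observed information.  statsmodels GLM serves as
  an independent oracle in the tests only.
* AUC: the rank statistic P(score_case > score_control) with ties
  counted ½ (Mann-Whitney U / n₁n₀); ROC curves threshold at every
  distinct score, tied scores moving diagonally so the trapezoidal area
  equals the rank AUC exactly.
* Effect summary: OR at two SD = exp(2·|β|) for a z-scored predictor,
  reported with the signed coefficient.
* Univariate comparator: two-sided Wilcoxon rank-sum per feature on its
  complete cases (exact for combined n ≤ 20 without ties, normal
  approximation with tie correction otherwise), Bonferroni-adjusted by
  the number of testable features.

## 6. Synthetic cohorts and what the tests show

The generator emulates the emulated study's shape: three classes
(default 48 HC / 98 MCI / 48 AD), ~650 features in modality blocks with
per-modality MCAR rates (MRI 5%, PET 10%, fluid assays 15%, clinical
2% — imaging is rarely missing once acquired, assays often are), ~10%
binary clinical flags thresholded from latent normals at prevalence
0.3, planted mean-shift features and correlated duplicates
(child = ρ·parent + √(1−ρ²)·ε, default ρ = 0.9, children inherit
parental missingness plus their own).  A feature planted for contrast
(A, B) separates those classes by exactly δ SD; the remaining class
sits on a linear disease gradient (stage order HC < MCI < AD).  With
identity within-class covariance the implied logistic coefficient of a
planted feature is its signed δ (single-feature population AUC
Φ(δ/√2)), which the parameter-recovery and AUC tests exploit.  The
standard recovery scenario — 5 planted features at δ = 1.5 among 600,
300 subjects per class — is the package's reference study condition.

Deliberately not emulated: real marginal distributions and units,
inter-modality correlation beyond the planted structure, informative
(MNAR) missingness, and label noise.  Passing tests therefore show the
*methodology* behaves as claimed under its own assumptions (it finds
what is there, at the stated error rates, reproducibly); they do not
show that any particular clinical dataset satisfies those assumptions.

## 7. Problem sizes used by the test suite

The full study design (1,000 GA runs × 300 generations, 1,000
bootstrap resamples, 1,000 random models) is the package default.  The
test and acceptance suites run the same code at reduced sizes chosen to
keep a complete run on a single CPU in minutes: 20 end-to-end
repetitions at 100 GA runs × 50 generations for recovery, 200 random
models × 200 resamples for the chance experiment, and 1,000 simulated
cohorts for IDI calibration.  The `--scaled-down` CLI flag applies the
same reductions.

## 8. Known limitations

* The calibration set contains the feature-selection subjects, so
  calibration-set bootstrap metrics are optimistic; the blind test set
  and the random-model null are the honest comparisons.  This mirrors
  the emulated design rather than correcting it.
* The IDI gate at 5% admits ~1 null feature per 20 candidates walked;
  backward elimination removes most but not all (the worked example in
  the README shows one surviving).  Panel size is not explicitly
  penalized.
* Frequencies from the GA are conditional on one dataset; they carry
  its sampling noise and should not be read as selection probabilities
  under resampling.
* The compiled fitness kernel trades tail convergence for speed; its
  fitted probabilities are not suitable for inference (the reference
  fitter is used everywhere outside GA fitness).
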