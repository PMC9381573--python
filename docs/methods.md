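# Methods

This note documents the models, procedures and numerical choices behind
`mrsdx`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cohort model

Real patient data for this problem are not publicly deposited, so every
stage is exercised on seeded synthetic cohorts. The generator draws,
per group *g* and metabolite *m*,

    x ~ Normal( mu_gm + beta_m · (age − age_center),  sigma_gm² ),
    age ~ Normal( mu_age_g, sigma_age_g² ) truncated at 18 years,

i.e. a Gaussian feature model with additive linear age effects. This is
deliberately the *simplest* model carrying the structure the study
population reports — group sizes, group age means ± SDs, linear age
regressions, and means ± SDs per metabolite; no higher moments or
between-metabolite covariances are modelled because none are reported.
Consequences:

* Passing tests demonstrate that the pipeline recovers *known* Gaussian
  group structure and stays at chance when none exists. They do not
  demonstrate performance on real spectra, where features are
  correlated (e.g. Glu/Gln crosstalk), non-Gaussian, and noisier in
  ways that depend on spectral quality.
* The packaged spec (`default_study_spec`) fixes the study conditions:
  HC n=24 (43 ± 15 y), RR-MS n=25 (45 ± 13 y), P-MS n=19 (55 ± 8.3 y);
  two missing GABA entries (one HC, one P-MS); age drift on
  tNAA (−0.020), Glu (−0.020), tCho (+0.005), mIns (+0.015) mM/year;
  baseline concentrations (mM re 10 mM tCr) Glu 9.0 ± 1.0,
  Gln 2.5 ± 0.5, GABA 1.20 ± 0.25, GSH 1.30 ± 0.25, tCho 1.8 ± 0.3,
  tNAA 11.0 ± 1.2, mIns 5.5 ± 0.9 — magnitudes a 7-T prefrontal voxel
  plausibly yields. The study's true group means are unknown, so the
  progressive-group effect is an explicit user parameter: a mean shift
  on GABA and Glu in pooled-SD units, default −0.8, 0 for a null
  cohort. Acceptance rests on property-based recovery under these
  stated conditions, never on mimicking the original cohort's numbers.
* Ages are truncated at 18 by redrawing, to avoid non-physical values;
  the age-centering constant is exposed (`age_center`, default the
  n-weighted mean of group age means) because raw-vs-centered age is
  not otherwise identified.
* Randomness: one master seed; per-group and per-purpose substreams are
  keyed by CRC32 of stable names, so adding a group or stage never
  perturbs existing draws, and row order never affects results.

## Preparation steps

**Age correction.** For each of tNAA, tCho, mIns and Glu, an OLS slope
of concentration on age is estimated *from the control group only*; if
its two-tailed p < 0.05 (the study-wide α), β·(age − mean control age)
is subtracted for all participants. Non-significant slopes leave the
metabolite untouched. Fewer than three control records is an error.

**Imputation.** Missing entries (two GABA cells in the packaged cohort)
are replaced by the mean of their three-level phenotype group, computed
over the whole cohort *before* any splitting — replicating the original
prior-to-analysis behaviour, which leaks a small amount of information
across splits. A leakage-safe alternative is available
(`imputation="train_only"`): missing training cells are filled from the
fold's own class means and a missing evaluation cell is set to the
fold's training mean (z-score 0). The default remains the replication
mode; the flag documents the deviation rather than silently fixing it.

**Scaling.** "Scaling by a matrix fitted on the training set" is read
as the diagonal case: per-feature z-scoring with training mean and
ddof-1 SD, transferred unchanged to the evaluation case. Full whitening
is rejected deliberately — it would reintroduce a rotation of the
feature space that the no-dimensionality-reduction stance avoids.
`fit_scaling` treats a zero-variance feature as an error; inside the
resampling loop a guarded variant maps zero SD to 1 so a degenerate
(constant) column scales to 0 instead of aborting a fold — a constant
carries no class information either way, and this keeps permutation
importance of such a column well-defined (exactly 0).

**SMOTE.** The minority class is oversampled to exact parity:
synthetic point = x_i + u·(x_nn − x_i), u ~ U(0,1), x_nn uniform among
the k nearest minority neighbors (k default 5, the technique's
conventional setting; exposed in config). Base cases are cycled so the
synthetic load spreads evenly. The pipeline order is: remove held-out
case → remove CV case → SMOTE → fit scaling on the augmented training
set → transfer. Because SMOTE therefore runs before scaling, the
neighbor metric standardizes columns internally (minority per-feature
SD); interpolation itself is affine-invariant, so only neighbor
identity depends on this choice. Whether the original analysis scaled
before or after balancing is not documented; this order follows the
pipeline description's sentence order and is switchable in code. If a
class has a single member (degenerate toy inputs only), it is balanced
by duplication, the k→0 limit of segment interpolation.

## Classifiers

All three families consume the scaled training matrix, emit a
continuous positively-oriented decision score, and predict its sign.

* **QDA** — per-class Gaussians: priors n_k/n, class means, and
  shrunken covariances Σ_k = (1−λ)S_k + λ·(tr S_k / N_f)·I. Shrinkage λ
  is the family's single optimized hyperparameter (grid
  {0, 10⁻³, 10⁻², 0.1, 0.3, 0.5}); it is required in practice for
  invertibility at n ≈ 20, p = 7. Score = g₊ − g₋ with
  g_k(x) = −½ln|Σ_k| − ½(x−μ_k)ᵀΣ_k⁻¹(x−μ_k) + ln π_k. λ = 0 on a
  singular class covariance raises an error advising λ > 0.
* **KNN** — majority vote among the k Euclidean-nearest scaled training
  points; score = (votes₊ − votes₋)/k ∈ [−1, 1]. k is odd (no vote
  ties); distance ties break to the lowest training index, which is
  deterministic because training rows are in canonical sorted-id order.
  Grid {1, 3, 5, 7, 9, 11}.
* **SVM** — soft-margin RBF dual, γ = s/(N_f·σ_x²) with σ_x² the
  overall variance of the scaled training matrix; grid over
  s ∈ {0.1, 0.5, 1, 2, 10} at C = 1. The dual solve is delegated to
  scikit-learn's SMO solver, but support vectors, α_i y_i, bias and γ
  are extracted and the decision function is evaluated from those
  stored arrays, so serialized models reproduce scores exactly and
  dual feasibility (0 ≤ α_i ≤ C, Σα_i y_i = 0) is checkable. The
  hyperparameter grids are package choices exposed in config — the
  original grids are not published.

Models serialize to JSON and round-trip with scores preserved to 1e-12.

## Resampling architecture

Outer balanced mode: every smaller-class case held out once plus an
equal-size sample (seeded, without replacement) of the larger class —
N₁ × 2 single-case runs, each training on all remaining cases. The
exhaustive mode (every case once) is also implemented because the two
published descriptions of the held-out population conflict; reports
name the mode used. Inner folds apply the same balanced scheme within
each training set (N₂ × 2).

Hyperparameters and features are selected **once per (task, family)**
on inner-fold statistics pooled across all outer training sets — the
aggregate/bootstrapping design — not re-optimized per outer run (a
fully nested re-optimization is out of scope by design). Selection ties
go to the simpler model: lowest k, highest shrinkage, smallest s, then
grid order. Permutation importance permutes a feature's raw values
across the pooled evaluation cases (each case re-scaled by its own
fold's transform and re-scored by its own fold's model), repeats
default 100 with a dedicated seed stream; the importance is the mean
accuracy drop, with its SD over repeats. Recursive elimination drops
the lowest-importance feature and keeps the reduction iff pooled CV
accuracy OR AUROC strictly improves, stopping at the first
non-improvement or one remaining feature; the full audit trail is
returned.

All split plans are canonicalised on sorted case ids, so every result
is invariant to input row order, and every stochastic stage draws from
a named substream of the master seed, so reruns agree bit-for-bit.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
recall = sensitivity, accuracy, F1 = 2PR/(P+R). Ratios with zero
denominators are reported as NaN ("not applicable"), never 0. ROC: the
score axis is swept at every distinct value (positive iff score ≥ t),
anchored at (0,0) and (1,1), ties collapsed to one threshold; AUROC is
the trapezoidal area, which equals the midrank Mann–Whitney statistic —
the test suite pins this equivalence. The cross-question accuracy
comparison is a pooled-variance two-sample t-test; the pooled variant
is the default because it reproduces the study's printed statistic,
and both df conventions (n₁+n₂−2, and min(n)−1 as printed there) are
emitted side by side since the published convention is ambiguous.

## Problem sizes used in checks

The packaged experiments run at the cohort's own scale (68
participants, 38–48 outer runs, ~1 400 pooled inner folds per
configuration). The chance-level control averages 20 null cohorts per
family with the family's default configuration and no feature
elimination — under the null, hyperparameter choice cannot manufacture
held-out signal, and this keeps the control cheap. The signal-recovery
experiment (2-pooled-SD GABA/Glu shifts) runs the full QDA shrinkage
grid over 10 cohorts with all seven features retained. Feature-
selection behaviour is checked separately on purpose-built cohorts
(one informative feature among six noise features, n = 30/30; all
features strongly informative, n = 16/16).

## Known limitations

* No between-metabolite covariance in the generator; pipelines that
  exploit correlations are not stressed.
* The paper-mode imputation deliberately reproduces a small information
  leak; use `train_only` for leakage-free estimates.
* SMOTE variants (borderline, ADASYN), multiclass wrappers, probability
  calibration, AUROC confidence intervals and the four discarded
  classifier families are out of scope.
* Balanced-mode results depend (mildly) on which larger-class cases the
  seed samples; the exhaustive mode removes that dependence at the cost
  of an unbalanced held-out population.
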