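# Methods

## The Pace-of-Aging composite

The composite summarizes each subject's physiological decline across a
19-biomarker panel observed at repeated waves (default design: ages 26,
32, 38, 45).

1. **Standardization.** Each biomarker is z-scored against its
   *baseline-wave* distribution (age 26), separately for men and women;
   all later waves are scaled by the same baseline mean and s.d., so a
   z-change of 1 means "one baseline s.d. of drift". The catalog's
   `decline_direction` (+1 higher-is-worse, −1 higher-is-better; e.g.
   VO₂max, HDL, FEV₁ and eGFR are flipped) is applied here, so larger z is
   always worse. Signs live in the catalog configuration, not in code,
   because which assays need flipping is a property of the panel, not of
   the algorithm.
2. **Growth slopes.** For each biomarker, a linear mixed model regresses z
   on age centered at baseline, with a random intercept and random slope
   per subject (REML, L-BFGS). The per-subject annual slope is the fixed
   slope plus the subject's BLUP. Centering age at baseline makes the
   intercept the baseline level and keeps standardization and slope
   fitting consistent. If the fitted residual variance collapses to ~0
   (noiseless or saturated designs, where BLUP shrinkage is meaningless
   and numerically fragile) the estimator falls back to exact per-subject
   OLS; `estimator="per_subject_ols"` selects that path directly and is
   the cheap choice for large simulation studies, since with four balanced
   waves the two estimators differ only through shrinkage of measurement
   noise. Subjects with fewer than two distinct waves for a biomarker are
   excluded from that biomarker's fit with a warning.
3. **Composition.** Slopes are summed with unit weights and the sum is
   divided by its cohort mean, giving year-equivalent units with cohort
   mean exactly 1. The mean-divide convention is a documented choice — it
   reproduces the interpretation "the average participant ages one
   physiological year per calendar year" exactly — rather than a claim
   about any particular study's internal scaling constant. A cohort whose
   mean slope sum is ≤ 0 has no year-equivalent interpretation and is
   rejected.

## The morphometrics → pace elastic net

**Feature space.** 315 features: 68 per cortical class (CT mm, SA mm²,
GMV mm³, GWR dimensionless; 34 Desikan–Killiany parcels × 2 hemispheres)
plus 43 segmentation volumes (mm³). The 43-entry subcortical block is the
standard aseg segmentation (14 bilateral structures, midline ventricles,
brain stem, CSF, optic chiasm, five corpus-callosum subregions,
whole-brain hypointensity totals, and two whole-brain volume summaries);
the four lateralized hypointensity measures are excluded by construction
for insufficient variance. A `no_gwr` variant (247 features) supports
datasets that do not distribute intensity ratios. Feature values are used
on their native scale; no unit conversion is attempted, because scoring
applies published-style raw-scale weights.

**Objective.** glmnet parameterization: `(1/2n)·RSS + λ(α‖β‖₁ +
(1−α)/2·‖β‖₂²)`, predictors internally standardized to unit (population)
variance, intercept unpenalized, coefficients reported on the original
feature scale. This is the convention under which published tuning values
such as α = 0.214, λ = 0.100 are meaningful; it maps exactly onto
scikit-learn's `ElasticNet(alpha=λ, l1_ratio=α)` on the standardized
design, which does the coordinate descent. λ = 0 is solved by least
squares directly.

**Tuning.** Repeated k-fold cross-validation (defaults 10 × 100) over an
(α, λ) grid. Folds are stratified by target decile and regenerated per
repetition from a seed sequence, which stabilizes small-fold variance and
makes every run reproducible. Within each training fold the target is
residualized on the covariates (sex by default) and the stored OLS
coefficients — never a refit — are applied to the held-out fold, so no
information flows from test to train; `fit_fold` exposes exactly this unit
and the test suite checks bitwise invariance of its output under held-out
corruption. Held-out R² is the squared Pearson correlation between
prediction and observation (the caret convention, matching how such
models are tuned in practice) with constant predictions scored 0; grid
points are ranked by mean R² with ties broken by lower MAE, a
deterministic reading of "highest variance explained and lowest mean
absolute error". The winner is refit on the full sample.

**Scoring and importance.** Scoring is the plain linear form
`intercept + Σ w_j x_j` on raw feature values; features with zero weight
may be absent, a missing nonzero-weight feature is a hard error (silent
imputation changes scores invisibly; an explicit opt-in mean-imputation
mode logs a warning). Feature importance is the Haufe encoding view,
`cov(x_j, reference)` with denominator n−1, against the observed target
by default (`model_prediction` gives the canonical model-based variant) —
interpretable where raw decoding weights of collinear features are not.

## Reliability

ICC(3,1) — two-way mixed-effects, single-measurement, consistency form —
from the ANOVA decomposition of the n×k score matrix:
`(MS_rows − MS_error)/(MS_rows + (k−1)·MS_error)`, with Shrout–Fleiss
F-based 95% bounds. A per-subject between-session interval, when given,
is treated as an effect of no interest by residualizing the stacked
scores on it (with intercept) before the ANOVA — the simplest faithful
implementation; it removes interval-correlated contamination of the
between-subject variance. Degenerate inputs: zero between-subject
variance yields ICC 0 with a warning; an exactly session-reproducible
matrix yields 1 (tiny negative error sums from floating point are
clamped).

## Validation statistics

* **Standardized associations**: outcome and exposure z-scored on the
  analysis sample (after listwise deletion, counts logged), covariates
  raw, OLS fit; CIs are the normal approximation β ± 1.96·se. With
  cluster ids the variance is the CR0 sandwich with a G/(G−1)
  small-sample factor (coded directly; the formula is short and the
  correction convention explicit).
* **Cox proportional hazards**: exposure z-scored so hazard ratios are
  per s.d.; partial likelihood maximized by lifelines with Efron tie
  handling at 1e-10 convergence precision. Only Efron ties are offered —
  the backend implements no alternative, and the test suite pins the
  estimate against an independently maximized Efron partial likelihood
  and against R's `coxph` conventions.
* **Atrophy slopes**: multilevel model of structure volume on age
  (random intercept + slope per participant); per-subject slope = fixed +
  BLUP, in mm³/year. Single-scan subjects are excluded with a warning.

## The synthetic generator

One latent rate θ_i ~ N(1, 0.3²), truncated below at 0.1, drives all
streams; sex is independent of θ by default so covariate residualization
is testable.

* Biomarker value = baseline_ij + d_j·s_j·θ_i·(age − 26) + noise, with
  s_j = 0.05 z-units/year per unit θ (≈ one baseline s.d. of drift over
  the 19-year window for the average subject — the scale on which such
  panels actually move) and observation noise s.d. 0.1.
* Morphometric feature k = class offset + class scale ×
  (a_k·brain_i + b_k·g_i + c·ε). `brain_i` is a brain-aging factor
  correlated `brain_specificity` with θ: morphometry measures brain
  aging, which is only partly the body's aging, and this single parameter
  caps the recoverable signal no matter how many features a model pools.
  g_i is a global nuisance factor (head-size/scanner-like) shared across
  features; signs follow brain-aging anatomy (negative loadings for
  thickness/area/volumes, positive for ventricles, CSF and
  hypointensities, positive pericalcarine intensity ratios).
* Retest adds independent session noise per feature; events follow an
  exponential hazard with log-hazard linear in θ and administrative
  censoring; a hippocampus-like volume declines at 30·θ mm³/year.

The `paper_like` preset (n = 860, brain_specificity 0.5, shared noise
1.7, independent noise 3.5, retest noise 0.2) was calibrated once so the
315-feature model's held-out correlation with the pace composite sits
mid-range of the moderate accuracies reported for MRI-based pace
estimators (≈ 0.4) while test–retest reliability stays excellent; the
suite asserts only the qualitative envelope (r in [0.35, 0.55], ICC ≥
0.9), not a point value.

What the generator does **not** emulate: scanner/site batch structure,
age-heterogeneous cohorts (all simulated subjects share the wave design),
non-linear trajectories, informative dropout, measurement floors/ceilings
and diagnosis-driven selection. Passing tests therefore demonstrate
algorithmic correctness and calibration under the stated generative
model, not performance on any real cohort.

## Problem sizes and runtimes

The test suite and acceptance script run on one CPU. Simulation sizes
were chosen as the smallest that make each check statistically sharp:
n = 500 for the composite's construction (mixed models dominate, ~1 min),
2,000 replicates for type-I-error calibration, n = 10,000 for
hazard-ratio recovery and for latent-distribution moments, n = 860 for
the realistic-preset envelope.

## Known limitations

* The exact membership of the 43-entry segmentation block follows the
  documented default above; a vendored published weights file, when
  available, is the authoritative list and can override the schema.
* The mixed-model slope estimator assumes linear trajectories; with only
  four waves that is also essentially what the data can identify.
* Cox models offer no Breslow tie option and no time-varying covariates.
* Scores are comparable within, not across, datasets; no normative
  calibration is provided.
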