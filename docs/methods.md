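# Methods

## Model

Regional brain volumes scale allometrically with head size. For a region
with volume `VOI` (cc) and intracranial volume `ICV` (cc), the package
models

    VOI = α · ICV^β + ε,     ε ~ N(0, σ²)  i.i.d. across subjects,

where α (cc per cc^β) is a scale constant, β is the dimensionless scaling
exponent and ε is **additive** noise: the scatter of a structure's volume
is assumed constant across head sizes, which matches what volumetric
scatterplots typically show. β = 1 is strict proportionality; β < 1 means
the structure grows sublinearly with the head. The power-proportion
correction divides each volume by `ICV^b` with `b` the fitted exponent, so
corrected volumes are uncorrelated with ICV by construction of the model;
with `b = 1` it collapses to the classical VOI/ICV ratio.

The log-log alternative (OLS of log VOI on log ICV) estimates the same
power relation but under **multiplicative** log-normal noise, implying
scatter that grows with ICV. Both are implemented; the additive form is the
default because homoscedasticity across ICV is what the data the model was
designed for exhibit. The synthetic generator can produce either noise
regime, and the test suite verifies the distinguishing signature (rank
correlation of absolute residuals with ICV: null under additive, positive
under multiplicative).

## Estimation

Nonlinear least squares by Levenberg–Marquardt (scipy `least_squares`,
analytic Jacobian `[ICV^β, α·ICV^β·ln ICV]`). Numerical choices:

* **Scaling.** ICV is divided by its sample geometric mean before fitting,
  so `ICV^β` stays O(1) for any plausible β; α and its SE are transformed
  back afterwards. β and its SE are invariant to this (tested).
* **Initialization.** Log-log OLS: slope → β₀, exp(intercept) → α₀. This is
  the closely related multiplicative-noise estimator and lands near the
  additive optimum, making the nonconvex fit reliable. An explicit
  `(α₀, β₀)` may be supplied (used to warm-start cross-validation refits).
* **Convergence.** Relative SSE change < 1e-10 (ftol), with step- and
  gradient-based termination as alternates; 200-iteration cap. On solver
  failure the fit falls back to a profile search — β on a grid over [0, 3]
  (step 1e-3) with α profiled in closed form, α(β) = Σ(VOI·ICV^β)/Σ(ICV^2β)
  — followed by a re-polish; if that also stalls the best point is returned
  with `converged=False`.
* **Uncertainty.** Gauss–Newton linearization: covariance σ̂²(JᵀJ)⁻¹ at the
  optimum, σ̂² = SSE/(n−2), df = n−2 (two mean-function parameters).
  Confidence intervals use the t quantile at df; at n = 141 the t and
  normal quantiles agree to two decimals. SE of α uses the delta method
  through the geometric-mean back-transform.
* **Nonproportionality flag.** A region is flagged when its CI for β
  excludes 1, with a closed-interval convention (an endpoint exactly at 1
  is *not* flagged) — conservative, and the boundary case does not arise in
  practice. No multiple-testing correction is applied across regions; users
  comparing many regions should be aware the flags are per-region
  marginal statements.
* **Degenerate inputs.** Constant ICV is unidentifiable (error); fewer than
  3 complete pairs is an error; constant VOI legitimately yields β = 0,
  α = mean(VOI). Fits require strictly positive volumes.

The brute-force profile search doubles as an independent oracle in the test
suite (implemented separately there): the optimizer's SSE must not exceed
the dense-grid minimum.

## Corrections

All five methods operate per region on complete (ICV, VOI) pairs:

| method | formula | output scale |
|---|---|---|
| power_proportion | VOI / ICV^b, b fitted (or supplied) | cc / cc^b |
| proportion | VOI / ICV | dimensionless |
| ancova_residual | residual of VOI ~ 1 + ICV (+ mean VOI) | cc |
| ancova_quadratic | residual of VOI ~ 1 + ICV + ICV² (+ mean VOI) | cc |
| loglog_residual | VOI / ICV^{b_log}, b_log from log-log OLS | cc / cc^b |

Residual methods are recentred at mean(VOI) by default so every method
returns volume-scale numbers; a flag returns raw residuals. The quadratic
design centres ICV before squaring for conditioning (predictions are
invariant to the centring point) and reports whether the quadratic
coefficient is significant at 0.05. The log-log correction is returned in
ratio form rather than as log-scale residuals so it is directly comparable
with the power-proportion output. The exponent may be estimated on a
reference subset (e.g. controls via the `group` column) and applied to
everyone; every corrected table records the parameters that produced it, so
any correction is exactly reproducible from its output file.

Diagnostic: `residual_slope` regresses corrected volume on ICV (simple OLS)
and reports slope, Pearson r and the two-sided p-value for zero slope. A
flat line is the success criterion for a correction.

## Model comparison

Leave-one-out cross-validation of the mean models (power law, linear,
quadratic): each subject is predicted from a model fitted without them and
squared errors are summed. For the OLS models the folds are computed
exactly via the leverage identity e_i/(1−h_ii) (PRESS), which equals the
explicit refit loop (asserted in tests against an independently coded
double loop). The power-law model is genuinely refit per fold,
warm-started from the full-data fit with a tightened SSE tolerance;
warm- and cold-start totals agree within 1e-6 (tested). Fold failures
(e.g. unit leverage, too few points) are recorded and excluded from the
total with a warning; they never abort a batch. Per-region summaries mark
the lowest-error model and whether the exponent CI excludes 1. Out-of-sample
error of the quadratic model is *not* guaranteed to be below the linear
model's (only the in-sample SSE nests); the suite asserts only the nesting
and directional Monte-Carlo statements.

## Synthetic cohorts

The generator emulates a single-scanner healthy-control cohort: 49 males
and 92 females; ICV per sex from normals with means (SD) 1712.01 (138.54)
and 1513.88 (122.12) cc; 43 regions (9 subcortical measures including CSF,
34 Desikan–Killiany cortical parcels) whose generating exponents equal
published control-sample estimates. Per region, α is placed so the typical
simulated volume is a plausible anatomical magnitude (e.g. caudate ≈ 3.5
cc) — these are round numbers, not estimates from any cohort — and σ is
calibrated so the fitted exponent's SE at n = 141 approximates the
published SE for that region. The calibration inverts the Gauss–Newton
variance formula on a fixed internal reference ICV sample and is therefore
approximate (realized SEs vary with the drawn ICVs, typically within ~20%
of target). Ages are drawn from the corresponding sex-specific normals and
floored at 18; they are annotation only.

Positivity is enforced by resampling nonpositive draws (the normal model
technically allows them); resample counts are logged so an unrealistic σ is
visible. Randomness is a single integer seed with per-region substreams
derived from hashed region names, so adding a region never perturbs the
draws of another and identical specs yield byte-identical tables.

What the generator does **not** emulate: segmentation artifacts and
heavy-tailed measurement error, age/disease effects on volumes,
between-region correlations within subject (regions are drawn
independently given ICV), scanner/site effects, and any real covariance
between ICV and demographics beyond sex. Passing tests therefore
demonstrate correctness of the estimation and comparison machinery under
the model's own assumptions, not robustness to real-data violations of
them.

## Problem sizes and simulation scale

Monte-Carlo checks in the tests and acceptance script use the cohort size
the method targets (n = 141) with 100–1000 replicates: 1000 replicates for
Wald-interval coverage (point estimate of coverage has SE ≈ 0.7 points),
100 replicates for the prediction-error comparisons, and n up to 10 000 for
consistency and law-of-large-numbers checks. These sizes give the
assertions comfortable statistical margins while keeping the default test
run fast.

## Known limitations

* Exponent SEs are first-order (linearization); for very noisy regions
  (e.g. ventricles) profile-likelihood intervals would be wider and
  asymmetric.
* Under the calibrated noise levels the cross-region correlation between
  fitted and generating exponents in a single simulated cohort is
  attenuated to ≈ 0.87 on average by estimation error; recovery should be
  judged by the within-2-SE rate, which is the calibrated quantity.
* Over a narrow ICV range (CV ≈ 10%) a power curve with β near 0.6–1 is
  locally close to a straight line, so LOOCV separates the power-law and
  linear mean models only weakly at realistic noise; the corrected-volume
  slope diagnostic is the more sensitive indicator of nonproportionality.
* No covariates beyond ICV (age, sex, site) are modelled; heteroscedastic
  and robust variants are out of scope.
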