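# Methods

## The problem and the two tracks

Obesity prevalence varies across the administrative districts of a large
city, and the drivers operate at two levels: individual behaviour and
circumstance (diet, weight-control history, blood pressure, income,
education, sleep), and the shared social/environmental fabric of a district
(green space, land price, transit use). The package implements one protocol
per level and a pipeline that runs both:

* **individual track** — preprocess → multicollinearity/significance screen
  → cross-validated classification → Shapley-value factor ranking per
  district;
* **district track** — geographically weighted LASSO (GWLASSO) regression of
  the district obesity rate on per-capita covariates, with spatially varying
  coefficients.

The original data sources for this kind of analysis are access-restricted,
so all development and validation run on the synthetic-data module, which
retains its generating truth for recovery tests.

## Synthetic-data generator

**Districts.** `n_districts` (default 25, the size of a large-city district
roster) centroids uniform on a 10×10 abstract planar region; populations
uniform in [80 000, 700 000]. Coordinates are planar, not geodetic, because
the spatial weighting downstream uses plain Euclidean distance; no geodesy is
implied or needed.

**District panel.** Covariates x_ik ~ N(0, 0.1²) i.i.d., standing for
centred per-capita quantities. The rate is
y_i = β₀(u_i,v_i) + Σ_k x_ik β_k(u_i,v_i) + ε_i, ε ~ N(0, noise_sd²)
(default 0.02), clipped to [0,1]. The default truth has six factors: three
strong single-signed surfaces (|β| ≥ 0.3 everywhere: green-park area and
land price negative, bus utilization positive), one mixed-sign surface
(bicycle utilization, ±0.25 across the region), and two exact zeros. The
intercept surface spans 0.29–0.33, so simulated rates land in the realistic
~20–40% band. The covariate scale of 0.1 is deliberate: with coefficients of
magnitude 0.3–0.5, unit-variance covariates would push a proportion far
outside [0,1] and clipping would destroy the linear structure the recovery
tests rely on. Gaussian additive noise on the rate is a modelling choice of
this module — nothing stronger is claimed for real survey-derived rates.

**Individuals.** Ordinal survey codes 1–5 (uniform) and 0/1 binaries;
a duplicate column (`stress_level_dup` = `stress_level`) to exercise VIF
pruning and two null features to exercise the significance screen. Codes
enter the logistic predictor centred and scaled to ~unit variance so effect
sizes are comparable. The label is Bernoulli in
logistic(intercept + Σ effects·scores); the default intercept −1.2 targets
~30% prevalence under the default effects. Height ~ N(1.65, 0.07²); weight
is back-computed from a BMI drawn in [25.5, 34] for obese records and
[19, 24.5] otherwise, so relabelling from height/weight reproduces the
latent label exactly (no probabilistic slack in round-trip tests).

**Two scenarios.** `default_truth()` is the realistic regime: moderate
effects, Bayes accuracy ≈ 0.79 — no classifier can beat that there, which is
itself a useful calibration fact. `strong_signal_truth()` scales the effects
×4 (intercept −2.5, prevalence ≈ 0.35, Bayes ≈ 0.93): the regime where a
well-fitted classifier reaches ~0.9 accuracy, used by the classification and
Shapley recovery checks. Passing tests on these generators demonstrates
protocol correctness and recoverability under known structure; they say
nothing about unmodelled features of real data (measurement error,
informative non-response, spatial autocorrelation of covariates, network
rather than Euclidean proximity).

## Preprocessing

BMI = weight/height² (kg/m²); obese ⇔ BMI ≥ 25, boundary inclusive (the
standard Asian-Pacific cut-point; inclusivity is our convention). Records
with a no-response sentinel (configurable, default −1) in any feature are
dropped whole. Per-capita normalization divides district aggregates by
population. Random oversampling duplicates minority records with
replacement to exact 1:1 — and is applied *only inside training folds*
during cross-validation, never before splitting, to keep test folds free of
resampling leakage. One consequence worth knowing: under a balanced-training
protocol the no-signal chance level of accuracy is ~1/2, not the
majority-class rate (which is the null only for the un-resampled protocol);
both nulls are asserted in the tests.

## Feature screening

VIF_j = 1/(1−R²_j) from an intercept-included OLS of feature j on the rest
(statsmodels); exact collinearity reports ∞ (sentinel 1e12). Iterative
pruning removes the single worst VIF above the threshold (default 30 — a
deliberately permissive level; 10 is the textbook cut but discards ordinal
survey items whose shared variance is weak) and recomputes, ties broken by
earliest column order; terminates in ≤ p steps. Then one joint OLS of the
0/1 label on all survivors (a linear-probability screen) drops features with
two-sided p > 0.05. Ordinal codes are treated as numeric — standard
survey-coding practice; dummy expansion is out of scope. The screen's
per-feature type-I rate is verified at ≈5% over 1,000 null simulations.

## Classification protocol

Four candidate families (logistic regression, random forest, XGBoost,
gradient boosting — sklearn/xgboost implementations; the bespoke content
here is the protocol, not the learners) under stratified 10-fold CV on
identical folds, ranked by pooled accuracy (ties: pooled F1, then spec
order). Stratification is our addition: at ~30% prevalence and small
per-district n, unstratified folds risk single-class training splits.
Metrics follow the confusion-table formulas; F1 is the harmonic mean of
precision and recall; zero-denominator metrics surface as explicit `None`
markers rather than silent zeros. Both pooled (summed confusion counts) and
fold-averaged metrics are emitted. The standalone random-forest default is
5,000 trees; desk-scale runs override it (see Pipeline).

## TreeSHAP

Exact path-dependent tree Shapley values, implemented here for sklearn
decision trees and random forests (attribution margin: class-1 probability;
forest values are the mean of per-tree values, matching the averaged
prediction). The algorithm keeps, along each root-to-leaf path, the features
split on together with the fraction of feature-subset permutations flowing
down the path, extending at splits (with an unwind step when a feature
repeats on the path) and reading off each feature's weighted contribution at
leaves; conditional expectations for excluded features follow training-cover
proportions. Local accuracy — base value + Σ attributions = prediction —
holds to machine precision and is enforced at 1e-6. Correctness is
additionally pinned by a brute-force oracle that enumerates all feature
subsets on small trees; the production path never shares code with the
oracle. The inner recursion is numba-jitted (~200 deep trees × 300 records
≈ 1 s); a pure-Python fallback keeps results identical, only slower.
Importance is the mean absolute attribution over records (the summary-plot
ordering), ties broken alphabetically so top-k tables are reproducible;
rankings are computed on all of a district's records by default, or a seeded
subsample for speed.

## GWLASSO

For each district i, with kernel weights w_ij on Euclidean inter-centroid
distances, solve

argmin_{β₀,β} Σ_j w_ij (y_j − β₀ − x_j·β)² + λ_i Σ_k |β_k|,

intercept unpenalized. Numerics:

* covariates are weighted-standardized (mean 0, variance 1 under the
  normalized weights) and y weighted-centred; the intercept is recovered by
  back-transform. Coefficients are reported on the standardized scale
  (comparable across factors) with the raw-scale back-transform alongside.
* cyclic coordinate descent with soft-thresholding; stopping at max
  coefficient change < 1e-10 or 10,000 sweeps; warm starts along the λ grid.
  The KKT conditions (|2Σ w x̃_k r| ≤ λ for zero coefficients, = λ with the
  coefficient's sign otherwise) are the correctness certificate, checked to
  1e-6; with this objective the full-shrinkage threshold is
  λ_max = 2·max_k |Σ w x̃_k ỹ|.
* kernels: Gaussian exp(−d²/2h²) (default — smooth weights suit n ≈ 25),
  bisquare with compact support, uniform (reduces every subproblem to the
  single global lasso, verified to 1e-8). Default bandwidth = median
  pairwise distance: scale-free and stable at this n; bandwidth
  cross-validation is out of scope.
* λ_i is selected on a 30-point log grid in [0.001, 0.03] by leave-one-out
  weighted prediction error (fit on the others, predict the held-out
  district, weight the squared error by its kernel weight); ties go to the
  larger, more parsimonious λ. LOO was chosen because n ≈ 25 makes it cheap
  and leaves no partitioning arbitrariness.
* degenerate inputs are rejected explicitly: all-zero weights, constant
  covariates under the weights, < 3 districts, out-of-range grids.

Summaries report each factor's min/mean/max coefficient over districts and
POS/NEG counts of strictly positive/negative districts; exact zeros —
which the L1 penalty produces — count in neither, so POS + NEG + zeros = n.

Known limitations: Euclidean distance ignores transport networks and
barriers; the per-district linear model with locally constant coefficients
is a smoothing approximation (a spatially varying intercept that correlates
with a covariate by chance leaks small bias into that covariate's local
coefficient at n = 25); the penalty range [0.001, 0.03] is inherited as a
fixed study setting and barely shrinks when the response scale is a
proportion with small noise — variable selection pressure is correspondingly
mild.

## Pipeline

`PipelineConfig` carries every threshold (BMI 25, VIF 30, α 0.05, 10 folds,
top-5, λ ∈ [0.001, 0.03]) and the compute knobs. The default configuration
is desk-scale — 25 districts, 5,000 individuals, 200 trees at depth ≤ 8,
SHAP on a 100-record subsample per district — sized so a full run completes
in about two minutes on one CPU; `PipelineConfig.paper_defaults()` restores
the 5,000-tree, unrestricted-depth classifier for full-scale runs.
Artifacts: per-district metric table with Total mean ± SD row, per-district
top-5 Shapley table, GWLASSO coefficient and summary tables, GeoJSON point
layers for mapping, and a run log with every seed and threshold. Identical
config and seed reproduce every CSV byte-for-byte; a failing stage aborts
with the stage's name in the error.

## Problem sizes used in checks

Solver certificates: 100 instances of n = 30, p = 5, λ ∈ [0, 0.05].
GWLASSO recovery: 10 seeded 25-district panels, p = 6 (2 true zeros),
noise 0.02. Screening: 1,000 null simulations of n = 500, p = 20.
Classification: 5,000 strong-signal records, 200-tree forest, 10 folds.
Shapley recovery: 20 seeded runs of 300 records, 40 trees, depth 5.
These sizes are the package's chosen desk-scale study conditions; the same
code runs unchanged at larger sizes.
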