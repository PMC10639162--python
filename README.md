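# obesifact

Two-track analysis of obesity-related factors for district-structured
populations, built for epidemiologists and health-geography researchers who
want the whole protocol — from raw survey-like records to spatially varying
coefficient maps — as reusable, tested Python.

**Individual track.** Survey records (coded responses plus height/weight) are
labelled obese at BMI ≥ 25 kg/m², screened for multicollinearity (iterative
variance-inflation-factor pruning at threshold 30) and significance (a joint
OLS linear-probability screen at α = 0.05), classified under stratified
10-fold cross-validation with training-fold-only random oversampling, and
explained with exact TreeSHAP: per-record Shapley attributions of each
feature on the obese-class probability, ranked by mean |attribution| per
district.

**District track.** A from-scratch **geographically weighted LASSO
(GWLASSO)** relates each district's obesity rate *y<sub>i</sub>* to
per-capita social/environmental covariates *x<sub>ik</sub>* with
location-specific coefficients: for each district *i*,

```
(β₀, β)(uᵢ,vᵢ) = argmin  Σⱼ w_ij (y_j − β₀ − Σₖ x_jk βₖ)²  +  λᵢ Σₖ |βₖ|
```

where *w<sub>ij</sub>* are kernel weights in the Euclidean distance between
district centroids (Gaussian, bisquare or uniform; default Gaussian at the
median pairwise distance), the intercept is unpenalized, and λ<sub>i</sub> is
chosen per district by leave-one-out weighted prediction error on a grid in
[0.001, 0.03]. The solver is cyclic coordinate descent with
soft-thresholding on weighted-standardized covariates, certified by the
weighted-lasso KKT conditions (residuals ≤ 1e-6 enforced in tests). With a
uniform kernel every district's solution collapses to the single global
lasso — a built-in consistency check.

The real study data (Korean community-health survey, credit-card aggregates,
municipal open data) are access-restricted, so the package ships a
first-class synthetic-data module: ~25 districts with smooth coefficient
surfaces and known truth, individual records with a known logistic effect
structure, ~30% obesity prevalence, plus injected pathologies (an exact
duplicate feature and true-null features) that the screening stage must
catch. Everything downstream is validated by recovering this retained truth.

## Worked example

`python examples/04_gwlasso_map.py` fits the GWLASSO on a 25-district
synthetic panel (noise sd 0.02) and prints:

```
bandwidth: 5.21 (median pairwise distance); selected penalties span [0.0083, 0.0300]

standardized coefficient summary (min/mean/max over 25 districts):
             factor     min    mean     max  pos  neg
    green_park_area -0.0546 -0.0481 -0.0387    0   25
         land_price -0.0458 -0.0435 -0.0409    0   25
    bus_utilization +0.0171 +0.0182 +0.0201   25    0
bicycle_utilization +0.0031 +0.0079 +0.0113   25    0
      health_budget -0.0005 +0.0024 +0.0066   21    2
 convenience_stores +0.0016 +0.0065 +0.0090   25    0

sign agreement with the generating surfaces for strong factors ['green_park_area', 'land_price', 'bus_utilization']: 100.0%
true-zero factors health_budget/convenience_stores stay near 0 (mean |beta_std| = 0.0044)
```

Each row is one factor's spatially varying coefficient: min/mean/max over
the 25 districts on the standardized scale, and POS/NEG counting districts
where it is strictly positive/negative (lasso zeros count in neither).
Green-park area and land price come out negative in all 25 districts and bus
utilization positive — matching the signs of the generating surfaces — while
the two factors with no true effect stay an order of magnitude smaller.

The other examples cover data synthesis (`01`), feature screening (`02`),
classifier comparison plus Shapley ranking (`03` — prints pooled
accuracy/precision/recall/F1 per model family and the top-5 factor table),
and the end-to-end pipeline (`05`), which writes `metrics.csv` (per-district
classification quality with a Total mean ± SD row), `top5.csv` (per-district
top factors), `gwlasso_summary.csv`, per-district coefficient tables, and
choropleth-ready GeoJSON.

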