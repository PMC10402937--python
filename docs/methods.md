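# Methods

`airrisk` implements a two-stage additive-risk analysis of long-term air
pollution exposure (PM2.5 in µg/m³, NO2 in ppb) and cancer incidence in an
open elderly cohort, together with a synthetic cohort generator that makes
every stage testable against known ground truth.

## The estimand and the analysis unit

The analysis unit is the **person-year**: one beneficiary's one calendar year
under observation after a 10-year cancer-free run-in. Each person-year `i`
carries six moving-average exposures — PM2.5 and NO2 over lag 0–2 years
(index year and two prior), lag 3–5, and lag 6–10 — a confounder vector
`c_i` (the *other five* exposure windows, individual covariates, and
ZIP-level community covariates), a death indicator `D_i`, and a
first-diagnosis indicator `Y_i`.

For one designated window `x`, the estimand is the **additive** effect: the
absolute change in annual diagnosis probability per unit of exposure,

    E(Y_i = 1 | x_i) = β₀ + β₁ x_i ,

so β₁ is a risk difference per µg/m³ (or per ppb), directly convertible to
an annual attributable case count

    annual cases = β₁ · N / duration ,

where `N` is the person-year denominator and `duration` the study span in
years (17 for a 2000–2016 study). Case counts are rounded half-away-from-zero
only at report time; confidence bounds are the same linear transform of β₁'s
bounds.

## Stage 1 — stabilized inverse-probability weights

The stabilized weight of person-year `i` is

    sw_i = K_num(x_i − x̄) / K_den(x_i − ĝ(x_i | c_i))
           × ĝ(D_i = 0 | x_i) / ĝ(D_i = 0 | x_i, c_i) .

* **Exposure model** ĝ(x|c): a gradient-boosted regression *initialized at
  the least-squares fit* (the booster is trained on OLS residuals).
  Pure boosted trees shrink smooth linear effects near the edges of the
  covariate range, which leaves residual confounding exactly where the
  weights matter most; the hybrid captures linear structure exactly and
  keeps the trees for nonlinearities and interactions. Defaults: 120 trees,
  learning rate 0.04, depth 3, subsample 0.8, ≥200 observations per leaf —
  deliberately regularized, because residuals from a heavily boosted
  in-sample fit are optimistically narrow, which makes the denominator
  density too peaked and deflates the weights. An optional held-out
  residual-scale calibration (`residual_scale_calibration`) is available as
  a safety net for aggressive configurations; at the defaults it measures a
  scale factor of ≈1.00 and is off.
* **Generalized propensity score**: the conditional density of the exposure
  is approximated by a Gaussian-kernel density of the exposure residuals
  (Silverman's rule-of-thumb bandwidth, configurable multiplier), and the
  numerator by a kernel density of the centered exposures. The two densities
  are fitted separately on their own samples so each is a proper density of
  its own argument; each fitted density is verified to integrate to 1 within
  1e-3. Densities are computed by FFT on a 4096-point grid extending 8
  bandwidths beyond the sample range and interpolated linearly; points
  beyond the grid are evaluated exactly.
* **Competing risk of death**: two boosted survival models, P(D=0|x) and
  P(D=0|x,c), fitted per person-year with binary (Bernoulli) loss by
  default; predictions are clipped to [1e-3, 1−1e-3]. A `gaussian_literal`
  mode (squared-loss regression on the 0/1 survival indicator, clipped) is
  provided as an alternative formulation. If a table contains no deaths the
  factor is identically 1 (with a warning).
* **Truncation** is off by default. Percentile capping concentrates on
  exactly the person-years that balance extreme confounder-exposure
  combinations; in validation, (1,99)-capping raised the weighted
  |correlation| between the exposure and the confounder driving it from
  ≈0.04 to ≈0.11 and biased β̂₁ accordingly, while the untruncated weights
  remained stable (effective sample size fraction ≈0.45–0.9). Capping
  remains available (`truncation=(1, 99)`) for pathologically heavy tails.

Diagnostics reported with every weight set: mean weight (raw and truncated),
maximum, Kish effective sample size (Σw)²/Σw², the exposure-model in-sample
R², bandwidths, and per-covariate weighted vs unweighted association with
the target exposure (Pearson correlation for continuous/binary covariates;
standardized mean differences across the weighted-median exposure split for
categorical levels), with a configurable flag threshold (default 0.1).

## Stage 2 — weighted linear probability model

Weighted least squares of `Y` on the single target exposure with the
stabilized weights. Standard errors are heteroskedasticity-robust and
clustered on the beneficiary (a person contributes several correlated
person-years); 95% intervals use β̂₁ ± 1.96·SE. A nonparametric cluster
bootstrap (per-person resampling) is provided as an alternative variance
estimator. Stage-1 estimation uncertainty is *not* propagated into stage-2
standard errors — the usual practice for estimated IPW, and a documented
limitation. Known degeneracies: all-zero outcomes give slope 0 with a
warning; micro-fits where the cluster sandwich is undefined fall back to
nonrobust SEs; zero weighted exposure variance is an error.

## Secondary analyses

Restriction analyses keep person-years whose three lag windows of the
analyzed pollutant are all *strictly below* a threshold (low-level:
10 µg/m³ PM2.5 / 20 ppb NO2; below-guideline: 5 µg/m³ / 10 ppb), then re-run
both stages from scratch inside the subset. The restriction applies to the
analyzed pollutant only (a both-pollutants mode is available). Subgroup
analyses split by a categorical axis, or by the lower (≤Q1) vs upper (≥Q3)
person-year quartile of a continuous community covariate; quartile strata
are disjoint by construction. Minimum-stratum guards (default 5,000
person-years and 20 events) emit an NA row with a reason code instead of a
meaningless fit. Every output row carries the full provenance (analysis
type, thresholds, subgroup, n, events, seed, config hash) needed to re-run
it bit-identically.

The attributable-case denominator for the main analysis defaults to analysis
person-years *plus* the observation years of beneficiaries excluded during
the run-in; both denominators are reported.

## The synthetic cohort generator

The generator emulates the structure the estimator assumes, with exported
ground truth:

* **Exposure surface**: annual ZIP-level concentrations for 1990–2016 (ten
  years before the cohort so every lag 6–10 window is complete).
  Within a ZIP: mean + linear trend + stationary AR(1) noise; across ZIPs:
  normally distributed means, shifted by `confounding_strength` per sd of
  the community deprivation covariate. Negative values are truncated at
  zero (an error if >10% truncate). Defaults:
  PM2.5 mean 9.8 µg/m³, spatial sd 0.5, AR(1) 0.5, innovation sd 1.9,
  trend −0.10/yr; NO2 mean 17.3 ppb, spatial sd 2.0, AR(1) 0.5, innovation
  sd 2.4, trend −0.30/yr; 1,500 ZIPs. The means match the observed national
  annual averages; the temporal/spatial split keeps the six windows
  informative but not collinear. The ZIP count matters more than it looks:
  exposures are constant within a ZIP-year, so the density ratio's
  effective sample is the number of distinct ZIP-years, and too few ZIPs
  visibly deflates the mean stabilized weight.
* **Population**: 50,000 beneficiaries by default; 90% enter at study start,
  the rest in later years that still allow the 10-year run-in. Sex (62%
  female), race (91/5.3/3.7% white/black/other), Medicaid (11%), age group
  at follow-up start (15% ≥85). Community covariates per ZIP: two
  standard-normal noise covariates and a centered unit-variance *uniform*
  deprivation index (bounded, so additive confounder effects keep annual
  probabilities in [0,1]).
* **Events**, per calendar year, death first and diagnosis among survivors
  (making death literally compete with diagnosis):
  death probability = 0.025 + 5e-4·PM2.5(current) + 0.04·(age ≥85) [+
  optional confounder terms]; diagnosis probability = β₀ + Σ β_w·x_w +
  Σ γ·c, with β₀ = 1.5e-4 and true effect 5e-5 per µg/m³ on PM2.5 lag 0–2
  by default (≈6×10⁻⁴ annual diagnosis probability at the mean exposure,
  a realistic single-cancer incidence for this age group). Probabilities
  are clipped to [0,1]; the run errors out if >1% of person-years required
  clipping, since that would invalidate the linear ground truth.
  Optional departures from global linearity (a steeper slope below a
  threshold; stratum-specific slope modifiers) support recovery tests of the
  restriction and subgroup analyses.
* **Named scenarios**: `scenario_unconfounded`;
  `scenario_confounded` (deprivation shifts exposure +1 unit/sd and risk
  +2e-4/sd); `scenario_death_confounded` (the same covariate additionally
  raises annual mortality by 0.015/sd).

What the generator deliberately does **not** emulate: daily time series,
real geodesy (ZIP polygons enter only through the optional grid-aggregation
path), cancer latency/staging, exposure measurement error, and unmeasured
confounding. Passing recovery tests therefore shows the estimator recovers
a known additive truth under correctly measured confounders — not that the
real-data associations are unbiased.

## Validation design and what it shows

Seeded Monte-Carlo batteries (20 replicates × 50,000 persons ≈ 200,000
person-years each) check: unconfounded recovery of β₁ within ±30% and
within Monte-Carlo error; predictable upward bias of the unweighted
estimator under confounding, removed by the weights; weight stabilization
(mean raw weight in [0.9, 1.1], ESS fraction ≥ 0.3); and exact oracle
equivalences (weighted normal equations; brute-force point-in-polygon
aggregation; the closed-form two-strata normal weight ratio, rank
correlation > 0.99 at a one-sd stratum separation). Printed-arithmetic
checks reproduce the published case conversions exactly.

On the competing-risk factor: under a *strictly additive* outcome and death
model, the survival-probability ratio provably shifts only the intercept of
the weighted regression, not the slope — with confounding weights applied,
both the with- and without-factor slopes attenuate equally (by the mean
within-year survival) and differ only at second order. The battery
therefore checks that the factor does not *hurt* recovery; a systematic
improvement is not implied by an additive generating process and should not
be expected from it.

## Numerical choices and known limitations

* Silverman bandwidths are near-optimal here; both under- and over-smoothing
  degraded the closed-form oracle agreement. At extreme stratum separations
  (≥2 sd) kernel tail bias degrades rank agreement with the closed-form
  weights to ≈0.98 — density-ratio weights are least reliable exactly where
  conditional densities are tiny.
* Diagnosis takes precedence when diagnosis and death fall in the same year
  (the diagnosis was observed first).
* Calendar-year granularity throughout; a person's event year is their last
  contributed person-year.
* "Below threshold" restrictions are strict (<); boundary person-years are
  rare and the convention is recorded in output metadata.
* Exposure ties within ZIP-years mean the kernel densities see ~10–30-fold
  duplicated points; bandwidths still use the person-year count (the
  density target is the person-year distribution), which is slightly
  undersmoothed but immaterial at ≥1,500 ZIPs.
* The six per-target analyses re-fit stage 1 from scratch with the other
  five windows as confounders; with strongly correlated windows the
  marginal/conditional variance ratio grows and weights get heavier — the
  ESS diagnostic is the guard.
* Monte-Carlo batteries and the reproduction script use modest replicate
  counts (20 and 5) at 50,000 persons; quantities reported from them carry
  the Monte-Carlo error of those sizes.
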