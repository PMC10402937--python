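# airrisk

Additive-risk analysis of long-term air pollution exposure and cancer
incidence, with stabilized inverse-probability weighting for a continuous
exposure and a competing risk of death — plus a synthetic open-cohort
generator so the whole pipeline can be validated against known ground truth
without restricted administrative data.

## Who this is for

Environmental epidemiologists and biostatisticians analyzing person-year
cohort data (e.g. Medicare-style claims cohorts) linked to annual ZIP-level
pollutant concentrations, who want *absolute* risk differences per unit of
PM2.5 (µg/m³) or NO2 (ppb) — and the annual attributable case counts they
imply — rather than hazard ratios.

## The method

The analysis unit is the person-year after a 10-year cancer-free run-in,
with six distributed-lag exposures per person-year: PM2.5 and NO2 moving
averages over lag 0–2, lag 3–5, and lag 6–10 years. For one target window
x with confounders c (including the other five windows), the analysis has
two stages:

**Stage 1 — design.** Each person-year gets a stabilized inverse-probability
weight

```
sw_i = K(x_i − x̄) / K(x_i − ĝ(x_i | c_i)) × ĝ(D_i=0 | x_i) / ĝ(D_i=0 | x_i, c_i)
```

where ĝ(x|c) is a gradient-boosted regression of the exposure on the
confounders (a generalized propensity score; the kernel density K of its
residuals avoids distributional assumptions) and the last factor — a ratio
of boosted survival models — stabilizes against the competing risk of death.

**Stage 2 — analysis.** A linear probability model weighted by the sw_i,

```
E(Y_i = 1 | x_i) = β₀ + β₁ x_i ,
```

so β₁ is the additive annual risk difference per unit exposure, with
cluster-robust (per-beneficiary) standard errors. It converts to cases via

```
annual cases = β₁ × N / duration
```

with N the person-year denominator and duration the study length in years.
Low-exposure restriction analyses (all three windows of the analyzed
pollutant strictly below 10 µg/m³ / 20 ppb, or below the WHO guideline
5 µg/m³ / 10 ppb) and subgroup analyses re-run both stages from scratch on
the stratum.

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

A single end-to-end run on a confounded synthetic cohort — community
deprivation raises both the PM2.5 exposure (+1 unit per sd) and the cancer
risk (+2e-4 per sd), and the true additive effect is 5e-5 per µg/m³ on the
lag 0–2 window:

```python
from airrisk import (
    scenario_confounded, simulate_cohort_data, build_cohort,
    DesignSpec, default_confounders, stabilized_weights,
    weighted_lpm, annual_cases,
)

config = scenario_confounded(n_individuals=50_000, seed=1)
tables = simulate_cohort_data(config)
cohort = build_cohort(tables["persons"], tables["zip_exposures"],
                      tables["zip_covariates"], study_end=2016)
py = cohort["person_years"]

spec = DesignSpec("pm25_lag02", default_confounders("pm25_lag02"), seed=1)
ws = stabilized_weights(py, spec)
naive = weighted_lpm(py, None, "pm25_lag02")
fit = weighted_lpm(py, ws, "pm25_lag02")
print(f"unweighted beta1 = {naive.beta1:.2e}")
print(f"IPW beta1        = {fit.beta1:.2e}  (truth 5.0e-05)")
print(f"mean weight {ws.diagnostics['mean_weight']:.3f}, "
      f"ESS fraction {ws.diagnostics['ess_fraction']:.3f}")
cases = annual_cases(fit, N=cohort['totals']['n_total'], duration=17)
print(f"annual cases per unit increase: {cases.annual_cases:.1f} "
      f"({cases.ci95[0]:.1f}, {cases.ci95[1]:.1f})")
```

Output:

```
unweighted beta1 = 5.99e-05
IPW beta1        = 3.35e-05  (truth 5.0e-05)
mean weight 0.956, ESS fraction 0.478
annual cases per unit increase: 0.6 (-0.4, 1.5)
```

One replicate carries substantial sampling noise (the per-replicate sd of
β̂₁ at ~210k person-years with ~130 events is ≈1.5e-5, so both estimates
here sit within ordinary sampling error of their expectations — this seed's
IPW draw happens to land low). The systematic picture needs replication:

```python
from airrisk._utils import spawn_seed
from airrisk.experiments import run_recovery_battery, summarize_battery
from airrisk.simulate import scenario_confounded

battery = run_recovery_battery(
    scenario_confounded, n_replicates=5, n_individuals=50_000,
    base_seed=spawn_seed(1, "confounded"),
)
s = summarize_battery(battery)
print(f"true beta1           = {s['beta_true']:.2e}")
print(f"unweighted mean      = {s['beta_unweighted_mean']:.2e}")
print(f"IPW-weighted mean    = {s['beta_ipw_mean']:.2e} "
      f"(Monte-Carlo se {s['beta_ipw_mc_se']:.1e})")
print(f"mean stabilized weight {s['mean_weight_raw']:.3f}, "
      f"ESS fraction {s['ess_fraction']:.3f}")
```

Output:

```
true beta1           = 5.00e-05
unweighted mean      = 9.61e-05
IPW-weighted mean    = 5.68e-05 (Monte-Carlo se 2.2e-05)
mean stabilized weight 0.965, ESS fraction 0.462
```

Across replicates the unweighted regression nearly doubles the true
coefficient (the deprivation covariate confounds it) while the weighted
mean sits within Monte-Carlo error of the truth, with stable weights
(mean ≈ 1) and nearly half the person-year information retained after
weighting. The annual-case line applies the β₁ × N / duration conversion
to the synthetic cohort's ~400k observation person-years.

A command-line interface mirrors the library:
`airrisk simulate`, `airrisk build`, `airrisk design`, `airrisk fit`, and
`airrisk run-all --config run.yaml` for a fully configured, seeded,
bit-reproducible end-to-end run.

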