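"""Secondary analyses: exposure restrictions and subgroup re-analyses.

Each variant re-runs the full two-stage pipeline (weights re-estimated from
scratch) on a filtered set of person-years:

* ``low_level`` keeps person-years with all three lag windows of the analyzed
  pollutant strictly below 10 ug/m3 (PM2.5) / 20 ppb (NO2);
* ``below_aqg`` uses the WHO Air Quality Guideline levels 5 ug/m3 / 10 ppb;
* ``subgroup`` analyses split by a categorical axis, or by the lower vs upper
  quartile of a continuous community covariate (quartiles over person-years,
  boundaries inclusive).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .additive import annual_cases, weighted_lpm
from .cohort import restrict_by_exposure
from .simulate import COMMUNITY_COLUMNS, WINDOW_NAMES
from .weights import DesignSpec, stabilized_weights

LOW_LEVEL_THRESHOLDS = {"pm25": 10.0, "no2": 20.0}
BELOW_AQG_THRESHOLDS = {"pm25": 5.0, "no2": 10.0}

SUBGROUP_AXES = ("age_group", "sex", "race", "medicaid") + tuple(COMMUNITY_COLUMNS)


@dataclass
class AnalysisPlan:
    """One analysis variant to run for each target exposure."""

    analysis_type: str = "main"  # main | low_level | below_aqg | subgroup
    thresholds: Mapping[str, float] | None = None
    restrict_both_pollutants: bool = False
    subgroup_axis: str | None = None
    min_person_years: int = 5_000
    min_events: int = 20

    def validate(self) -> None:
        if self.analysis_type not in ("main", "low_level", "below_aqg", "subgroup"):
            raise ValueError(f"unknown analysis_type {self.analysis_type!r}")
        if self.analysis_type == "subgroup":
            if self.subgroup_axis not in SUBGROUP_AXES:
                raise ValueError(f"unknown subgroup axis {self.subgroup_axis!r}")
        if self.thresholds is not None and any(v <= 0 for v in self.thresholds.values()):
            raise ValueError("thresholds must be positive")

    def resolved_thresholds(self) -> Mapping[str, float]:
        if self.thresholds is not None:
            return self.thresholds
        if self.analysis_type == "low_level":
            return LOW_LEVEL_THRESHOLDS
        if self.analysis_type == "below_aqg":
            return BELOW_AQG_THRESHOLDS
        return {}


def _fit_row(
    person_years: pd.DataFrame,
    spec: DesignSpec,
    n_for_cases: float,
    duration: float,
    label: dict,
) -> dict:
    """Run stage 1 + stage 2 on one (sub)set and return a result row."""
    weights = stabilized_weights(person_years, spec)
    fit = weighted_lpm(person_years, weights, spec.target_exposure)
    pollutant = spec.target_exposure.split("_")[0]
    cases = annual_cases(
        fit, n_for_cases, duration, pollutant=pollutant, window=spec.target_exposure
    )
    return {
        **label,
        "target": spec.target_exposure,
        "n_person_years": len(person_years),
        "n_events": int(person_years["Y"].sum()),
        "beta0": fit.beta0,
        "beta1": fit.beta1,
        "se_beta1": fit.se_beta1,
        "ci_low": fit.ci95[0],
        "ci_high": fit.ci95[1],
        "annual_cases": cases.annual_cases,
        "cases_ci_low": cases.ci95[0],
        "cases_ci_high": cases.ci95[1],
        "N_denominator": n_for_cases,
        "duration": duration,
        "mean_weight": weights.diagnostics["mean_weight"],
        "ess_fraction": weights.diagnostics["ess_fraction"],
        "n_flagged_covariates": weights.diagnostics["n_flagged_covariates"],
        "seed": spec.seed,
        "reason": "",
    }


def _na_row(spec: DesignSpec, label: dict, reason: str, n: int, events: int) -> dict:
    return {
        **label,
        "target": spec.target_exposure,
        "n_person_years": n,
        "n_events": events,
        **{
            k: np.nan
            for k in (
                "beta0",
                "beta1",
                "se_beta1",
                "ci_low",
                "ci_high",
                "annual_cases",
                "cases_ci_low",
                "cases_ci_high",
                "N_denominator",
                "duration",
                "mean_weight",
                "ess_fraction",
            )
        },
        "n_flagged_covariates": 0,
        "seed": spec.seed,
        "reason": reason,
    }


def _guarded_fit(
    subset: pd.DataFrame,
    plan: AnalysisPlan,
    spec: DesignSpec,
    n_for_cases: float,
    duration: float,
    label: dict,
) -> dict:
    events = int(subset["Y"].sum()) if len(subset) else 0
    if len(subset) < max(plan.min_person_years, 2):
        return _na_row(spec, label, "too_few_person_years", len(subset), events)
    if events < plan.min_events:
        reason = "no_events" if events == 0 else "too_few_events"
        return _na_row(spec, label, reason, len(subset), events)
    return _fit_row(subset, spec, n_for_cases, duration, label)


def run_restricted(
    person_years: pd.DataFrame,
    plan: AnalysisPlan,
    spec: DesignSpec,
    n_excluded_person_years: int = 0,
    duration: float = 17.0,
) -> pd.DataFrame:
    """Run one restricted (or main) analysis for one target exposure.

    Restriction applies to the analyzed pollutant's three lag windows (all
    strictly below the threshold); ``restrict_both_pollutants`` additionally
    filters the other pollutant at its own threshold.  The weight model is
    re-estimated within the restricted subset.  The attributable-case
    denominator is the subset's person-years plus (for the main analysis) the
    excluded persons' observation years.
    """
    plan.validate()
    spec.validate()
    thresholds = plan.resolved_thresholds()
    subset = person_years
    pollutant = spec.target_exposure.split("_")[0]
    if thresholds:
        pollutants = list(thresholds) if plan.restrict_both_pollutants else [pollutant]
        for p in pollutants:
            subset = restrict_by_exposure(subset, p, thresholds[p])
    n_for_cases = len(subset) + (
        n_excluded_person_years if plan.analysis_type == "main" else 0
    )
    label = {
        "analysis_type": plan.analysis_type,
        "subgroup": "",
        "thresholds": ";".join(f"{k}<{v}" for k, v in thresholds.items()) or "",
    }
    row = _guarded_fit(subset, plan, spec, max(n_for_cases, 1), duration, label)
    return pd.DataFrame([row])


def run_subgroups(
    person_years: pd.DataFrame,
    axis: str,
    plan: AnalysisPlan,
    spec: DesignSpec,
    duration: float = 17.0,
) -> pd.DataFrame:
    """Run the full pipeline separately within each level of ``axis``.

    Categorical axes use their observed levels; continuous community
    covariates are split into the lower (<= Q1) and upper (>= Q3) quartiles of
    the person-year distribution, which are disjoint by construction.  A sex
    axis requires both sexes to be present (single-sex cohorts have no sex
    subgroup analysis).
    """
    plan.validate()
    spec.validate()
    if axis not in person_years.columns:
        raise KeyError(f"axis {axis!r} not in the person-year table")
    if axis in spec.confounder_columns and axis not in COMMUNITY_COLUMNS:
        pass  # categorical axis may stay among confounders of other strata

    rows = []
    if axis in COMMUNITY_COLUMNS:
        q1, q3 = person_years[axis].quantile([0.25, 0.75])
        strata = {
            "lower_quartile": person_years[axis] <= q1,
            "upper_quartile": person_years[axis] >= q3,
        }
    else:
        levels = sorted(person_years[axis].astype(str).unique())
        if axis == "sex" and len(levels) < 2:
            raise ValueError(
                "sex subgroup analysis requires a cohort with both sexes"
            )
        strata = {lvl: person_years[axis].astype(str) == lvl for lvl in levels}

    for name, mask in strata.items():
        subset = person_years.loc[mask].reset_index(drop=True)
        # a single-level stratum makes that covariate degenerate; the design
        # matrix keeps it and the balance report flags it as degenerate
        label = {
            "analysis_type": "subgroup",
            "subgroup": f"{axis}={name}",
            "thresholds": "",
        }
        rows.append(
            _guarded_fit(subset, plan, spec, max(len(subset), 1), duration, label)
        )
    return pd.DataFrame(rows)


def default_confounders(target_exposure: str) -> list[str]:
    """The confounder set for one target: the other five lag windows plus the
    individual and community covariates."""
    others = [w for w in WINDOW_NAMES if w != target_exposure]
    return others + ["sex", "race", "medicaid", "age_group"] + list(COMMUNITY_COLUMNS)
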