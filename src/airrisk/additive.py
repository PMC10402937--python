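"""Stage 2: IPW-weighted linear probability model and attributable cases.

The additive association is estimated by weighted least squares of the
diagnosis indicator on the single target exposure,

    E(Y_i = 1 | x_i) = beta0 + beta1 * x_i,

so beta1 is an absolute risk difference per unit exposure (per ug/m3 of PM2.5
or per ppb of NO2).  The coefficient converts to the annual number of new
cases attributable to a unit increase in exposure via

    annual cases = beta1 * N / duration,

with N the person-year denominator and duration the study length in years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import round_half_away
from .weights import WeightSet

#: normal 95% critical value, used for all reported intervals
Z95 = 1.96


@dataclass
class AdditiveFit:
    """Weighted linear-probability fit for one target exposure."""

    beta0: float
    beta1: float
    se_beta1: float
    ci95: tuple[float, float]
    n_person_years_analysis: int
    variance_method: str
    target_exposure: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.beta1 <= hi):
            raise ValueError("beta1 must lie inside its confidence interval")


@dataclass
class CaseEstimate:
    """Annual attributable cases implied by an additive fit."""

    annual_cases: float
    ci95: tuple[float, float]
    N_denominator: float
    duration: float
    pollutant: str = ""
    window: str = ""
    cohort: str = ""

    @property
    def reported(self) -> int:
        """Integer case count, rounded half away from zero (report style)."""
        return round_half_away(self.annual_cases)


def weighted_lpm(
    person_years: pd.DataFrame,
    weights: WeightSet | np.ndarray | None,
    target_exposure: str,
    cluster_col: str = "person_id",
) -> AdditiveFit:
    """Weighted least squares of Y on the target exposure.

    Standard errors are heteroskedasticity-robust and clustered on the
    beneficiary (a person contributes several correlated person-years); the
    95% CI is beta1 +/- 1.96 se.  ``weights=None`` or all-equal weights give
    the ordinary least-squares fit.
    """
    if weights is None:
        w = np.ones(len(person_years))
    elif isinstance(weights, WeightSet):
        w = weights.sw
    else:
        w = np.asarray(weights, float)
    if w.size != len(person_years):
        raise ValueError("weights must align 1:1 with person-years")

    x = person_years[target_exposure].to_numpy(float)
    y = person_years["Y"].to_numpy(float)
    wmean = np.average(x, weights=w)
    if np.average((x - wmean) ** 2, weights=w) <= 0:
        raise ValueError("zero weighted exposure variance")
    if y.sum() == 0:
        warnings.warn(
            "no diagnoses among the person-years; slope is 0 with a degenerate SE",
            stacklevel=2,
        )

    X = sm.add_constant(x)
    groups = person_years[cluster_col].to_numpy()
    if len(person_years) > 2 and np.unique(groups).size >= 2:
        res = sm.WLS(y, X, weights=w).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
        variance_method = "cluster_robust_person"
    else:  # degenerate micro-fit: the sandwich correction is undefined
        res = sm.WLS(y, X, weights=w).fit()
        variance_method = "nonrobust"
    beta0, beta1 = (float(v) for v in res.params)
    se = float(res.bse[1])
    if not np.isfinite(se):
        se = 0.0
    return AdditiveFit(
        beta0=beta0,
        beta1=beta1,
        se_beta1=se,
        ci95=(beta1 - Z95 * se, beta1 + Z95 * se),
        n_person_years_analysis=int(len(person_years)),
        variance_method=variance_method,
        target_exposure=target_exposure,
    )


def cluster_bootstrap_se(
    person_years: pd.DataFrame,
    weights: WeightSet | np.ndarray,
    target_exposure: str,
    n_boot: int = 200,
    seed: int = 0,
    cluster_col: str = "person_id",
) -> float:
    """Nonparametric cluster bootstrap SE for beta1 (per-person resampling).

    Offered as an alternative to the sandwich variance; stage-1 estimation
    uncertainty is not propagated in either method.
    """
    w = weights.sw if isinstance(weights, WeightSet) else np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    ids = person_years[cluster_col].to_numpy()
    uniq = np.unique(ids)
    # rows of each cluster, precomputed
    order = np.argsort(ids, kind="stable")
    sorted_ids = ids[order]
    starts = np.searchsorted(sorted_ids, uniq, side="left")
    stops = np.searchsorted(sorted_ids, uniq, side="right")
    x = person_years[target_exposure].to_numpy(float)
    y = person_years["Y"].to_numpy(float)

    betas = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, uniq.size, uniq.size)
        rows = np.concatenate([order[starts[i] : stops[i]] for i in pick])
        xw, yw, ww = x[rows], y[rows], w[rows]
        xm = np.average(xw, weights=ww)
        ym = np.average(yw, weights=ww)
        betas[b] = np.sum(ww * (xw - xm) * (yw - ym)) / np.sum(ww * (xw - xm) ** 2)
    return float(betas.std(ddof=1))


def annual_cases(
    fit: AdditiveFit,
    N: float,
    duration: float,
    pollutant: str = "",
    window: str = "",
    cohort: str = "",
) -> CaseEstimate:
    """Convert an additive fit into annual attributable cases.

    ``annual_cases = beta1 * N / duration`` exactly, with the CI bounds
    transformed identically; rounding to an integer happens only at report
    time (half away from zero).
    """
    if N <= 0 or duration <= 0:
        raise ValueError("N and duration must be positive")
    scale = N / duration
    lo, hi = fit.ci95
    return CaseEstimate(
        annual_cases=fit.beta1 * scale,
        ci95=(lo * scale, hi * scale),
        N_denominator=N,
        duration=duration,
        pollutant=pollutant,
        window=window or fit.target_exposure,
        cohort=cohort,
    )


def combine_windows(estimates: Sequence[CaseEstimate]) -> float:
    """Sum the annual-case point estimates of the three lag windows of one
    pollutant (no CI is combined).  Raises on mismatched pollutant/cohort or
    duplicated windows."""
    if len(estimates) != 3:
        raise ValueError("expected exactly three window estimates")
    pollutants = {e.pollutant for e in estimates}
    cohorts = {e.cohort for e in estimates}
    windows = [e.window for e in estimates]
    if len(pollutants) != 1 or len(cohorts) != 1:
        raise ValueError("estimates must come from the same cohort and pollutant")
    if len(set(windows)) != 3:
        raise ValueError("estimates must cover three distinct windows")
    return float(sum(e.annual_cases for e in estimates))
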