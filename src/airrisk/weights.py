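"""Stage 1: stabilized inverse-probability weights for a continuous exposure.

For a designated exposure window x with confounders c (which include the other
five lag windows), the stabilized weight of person-year i is

    sw_i = K_num(x_i - xbar) / K_den(x_i - g(x_i | c_i))
           * g(D_i = 0 | x_i) / g(D_i = 0 | x_i, c_i)

where g(.|c) is a gradient-boosted regression of the exposure on the
confounders, K_num is a Gaussian kernel density fitted to the centered
exposures, K_den a kernel density fitted to the exposure residuals (the
generalized-propensity-score factor), and the last ratio of boosted
survival-probability models is the stabilizing factor for the competing risk
of death.  The numerator and denominator densities are fitted separately on
their own samples so that each is a proper density of its own argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.kde import KDEUnivariate


@dataclass(frozen=True)
class GbmParams:
    """Gradient-boosting hyperparameters (exposure and death models).

    The defaults are deliberately regularized: residuals from a heavily
    boosted in-sample fit are optimistically narrow, which makes the
    denominator density of the generalized propensity score too peaked and
    destabilizes the weights.  ``loss`` applies to the two death models:
    ``bernoulli`` fits a boosted classifier for survival, ``gaussian_literal``
    regresses the 0/1 survival indicator with squared loss and clips the
    predictions into (0, 1).
    """

    n_trees: int = 120
    learning_rate: float = 0.04
    max_depth: int = 3
    subsample: float = 0.8
    min_child_samples: int = 200
    loss: str = "bernoulli"

    def validate(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.loss not in ("bernoulli", "gaussian_literal"):
            raise ValueError("loss must be 'bernoulli' or 'gaussian_literal'")


@dataclass(frozen=True)
class KdeParams:
    kernel: str = "gaussian"
    bandwidth_rule: str = "silverman"
    adjust: float = 1.0

    def validate(self) -> None:
        if self.kernel != "gaussian":
            raise ValueError("only the gaussian kernel is supported")
        if self.bandwidth_rule != "silverman":
            raise ValueError("only Silverman's bandwidth rule is supported")
        if self.adjust <= 0:
            raise ValueError("bandwidth adjust must be positive")


@dataclass
class DesignSpec:
    """Specification of one stage-1 design (one target exposure window).

    ``truncation`` caps the raw weights at the given percentiles.  It is off
    by default: percentile capping concentrates on exactly the person-years
    that balance extreme confounder-exposure combinations, and measurably
    degrades weighted covariate balance at moderate effective sample sizes;
    it remains available for pathologically heavy-tailed weights.

    ``residual_scale_calibration`` rescales the in-sample exposure residuals
    to an honest conditional scale estimated on held-out halves before the
    denominator density is fitted -- a safety net for aggressive boosting
    configurations whose in-sample residuals are optimistically narrow.
    """

    target_exposure: str
    confounder_columns: Sequence[str]
    gbm_params: GbmParams = field(default_factory=GbmParams)
    kde_params: KdeParams = field(default_factory=KdeParams)
    truncation: tuple[float, float] | None = None
    residual_scale_calibration: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.target_exposure in self.confounder_columns:
            raise ValueError("target exposure must not appear among confounders")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not (0.0 <= lo < hi <= 100.0):
                raise ValueError("truncation percentiles must satisfy 0 <= lo < hi <= 100")
        self.gbm_params.validate()
        self.kde_params.validate()


@dataclass
class WeightSet:
    """Stabilized weights plus their components and diagnostics.

    ``components`` holds the four factors per person-year (numerator and
    denominator densities, death-model numerator and denominator); their
    ratio-product equals ``sw_raw`` exactly, and ``sw`` is the (optionally
    percentile-truncated) weight used downstream.
    """

    sw: np.ndarray
    sw_raw: np.ndarray
    components: pd.DataFrame
    diagnostics: dict

    def __len__(self) -> int:
        return self.sw.size


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, float)
    return float(w.sum() ** 2 / (w**2).sum())


# ---------------------------------------------------------------------------
# kernel density estimation
# ---------------------------------------------------------------------------


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.349) n^(-1/5)."""
    v = np.asarray(values, float)
    sd = v.std(ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("zero-variance input: bandwidth undefined")
    return 0.9 * spread * v.size ** (-0.2)


class GaussianKDE:
    """Gaussian-kernel density with Silverman bandwidth, evaluable anywhere.

    Fitted on a grid by FFT for speed and interpolated linearly; points beyond
    the grid (8 bandwidths past the sample range) are evaluated exactly.  The
    fitted density is verified to integrate to 1 within 1e-3 over the support.
    """

    def __init__(self, values, params: KdeParams | None = None, bandwidth: float | None = None):
        params = params or KdeParams()
        params.validate()
        v = np.asarray(values, float)
        if v.size < 2:
            raise ValueError("need at least two values for a density estimate")
        if bandwidth is not None:
            if bandwidth <= 0:
                raise ValueError("bandwidth must be positive")
            self.bandwidth = float(bandwidth)
        else:
            self.bandwidth = silverman_bandwidth(v) * params.adjust
        self._values = v
        kde = KDEUnivariate(v)
        kde.fit(kernel="gau", bw=self.bandwidth, fft=True, gridsize=2**12, cut=8)
        self._support = np.asarray(kde.support)
        self._density = np.asarray(kde.density)
        integral = float(np.trapezoid(self._density, self._support))
        if abs(integral - 1.0) > 1e-3:
            raise RuntimeError(
                f"kernel density integrates to {integral:.6f}, not 1 within 1e-3"
            )
        self.integral = integral

    def __call__(self, points) -> np.ndarray:
        p = np.atleast_1d(np.asarray(points, float))
        out = np.interp(p, self._support, self._density, left=np.nan, right=np.nan)
        outside = np.isnan(out)
        if outside.any():
            out[outside] = self._exact(p[outside])
        return out

    def _exact(self, points: np.ndarray) -> np.ndarray:
        h = self.bandwidth
        out = np.empty(points.size)
        for i, pt in enumerate(points):
            out[i] = stats.norm.pdf((pt - self._values) / h).mean() / h
        return out


def kde(values, params: KdeParams | None = None, bandwidth: float | None = None) -> GaussianKDE:
    """Fit a Gaussian kernel density; returns a callable density function."""
    return GaussianKDE(values, params, bandwidth=bandwidth)


# ---------------------------------------------------------------------------
# boosted models
# ---------------------------------------------------------------------------


def _design_matrix(
    person_years: pd.DataFrame, columns: Sequence[str]
) -> pd.DataFrame:
    """Numeric design matrix; categorical/string columns are one-hot encoded
    with a deterministic column order."""
    X = person_years[list(columns)]
    obj_cols = [c for c in X.columns if X[c].dtype == object or str(X[c].dtype) == "category"]
    X = pd.get_dummies(X, columns=obj_cols, drop_first=True, dtype=float)
    return X.reindex(sorted(X.columns), axis=1).astype(float)


def _lgbm_common(params: GbmParams, seed: int) -> dict:
    return dict(
        n_estimators=params.n_trees,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        num_leaves=2**params.max_depth,
        subsample=params.subsample,
        subsample_freq=1 if params.subsample < 1.0 else 0,
        min_child_samples=params.min_child_samples,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )


class _MeanModel:
    """Null boosted model (0 trees): predicts the training mean exactly."""

    def __init__(self, mean: float):
        self.mean = float(mean)

    def predict(self, X):
        return np.full(len(X), self.mean)


class _LinearBoostedModel:
    """Gradient-boosted regression initialized at the least-squares fit.

    The booster is trained on the residuals of an ordinary least-squares fit,
    so linear confounder-exposure structure is captured exactly while the
    trees pick up the remaining nonlinearities and interactions.  (Boosted
    trees alone shrink smooth linear effects at the edges of the covariate
    range, which leaves residual confounding exactly where the weights matter
    most.)
    """

    def __init__(self, booster, ols_coef: np.ndarray):
        self.booster = booster
        self.ols_coef = ols_coef

    @staticmethod
    def _augment(X: pd.DataFrame) -> np.ndarray:
        return np.column_stack([np.ones(len(X)), X.to_numpy(float)])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        pred = self._augment(X) @ self.ols_coef
        if self.booster is not None:
            pred = pred + self.booster.predict(X)
        return pred

    @classmethod
    def fit(cls, X: pd.DataFrame, y: np.ndarray, params: GbmParams, seed: int):
        import lightgbm as lgb

        A = cls._augment(X)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        booster = None
        if params.n_trees > 0:
            booster = lgb.LGBMRegressor(
                objective="regression", **_lgbm_common(params, seed)
            )
            booster.fit(X, y - A @ coef)
        return cls(booster, coef)


def fit_exposure_model(
    person_years: pd.DataFrame, spec: DesignSpec
) -> tuple[object, np.ndarray, float]:
    """Regression of the target exposure on all confounders.

    A gradient-boosted model initialized at the least-squares fit (see
    :class:`_LinearBoostedModel`).  Returns ``(model, residuals,
    in_sample_r2)`` where ``residuals = x - g(x | c)``.  With
    ``n_trees = 0`` the prediction is exactly the sample mean.
    """
    spec.validate()
    x = person_years[spec.target_exposure].to_numpy(float)
    if np.unique(x).size < 2:
        raise ValueError("constant exposure column: weights are undefined")
    X = _design_matrix(person_years, spec.confounder_columns)
    if X.isna().any(axis=None):
        raise ValueError("missing confounder values")
    if spec.gbm_params.n_trees == 0:
        model: object = _MeanModel(x.mean())
    else:
        model = _LinearBoostedModel.fit(X, x, spec.gbm_params, spec.seed)
    pred = model.predict(X)
    residuals = x - pred
    var_x = x.var()
    r2 = float(1.0 - residuals.var() / var_x) if var_x > 0 else 0.0
    return model, residuals, r2


def honest_residual_scale(person_years: pd.DataFrame, spec: DesignSpec) -> float:
    """Held-out estimate of the conditional residual sd of the exposure model.

    Fits the boosted exposure model on each half of the data and measures the
    residual sd on the opposite half; returns the pooled held-out sd.  Used to
    rescale the (optimistically narrow) in-sample residuals so that the
    denominator kernel density has the correct scale.
    """
    x = person_years[spec.target_exposure].to_numpy(float)
    X = _design_matrix(person_years, spec.confounder_columns)
    n = x.size
    rng = np.random.default_rng(spec.seed)
    half = rng.permutation(n) < n // 2
    sq_sum, n_tot = 0.0, 0
    for train in (half, ~half):
        if spec.gbm_params.n_trees == 0:
            pred = np.full(int((~train).sum()), x[train].mean())
        else:
            model = _LinearBoostedModel.fit(
                X[train], x[train], spec.gbm_params, spec.seed + 3
            )
            pred = model.predict(X[~train])
        err = x[~train] - pred
        sq_sum += float(((err - err.mean()) ** 2).sum())
        n_tot += err.size
    return float(np.sqrt(sq_sum / max(n_tot - 2, 1)))


_PROB_CLIP = 1e-3


def fit_death_models(
    person_years: pd.DataFrame, spec: DesignSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Survival-probability models for the competing-risk factor.

    Fits g(D=0 | x) on the target exposure alone (numerator) and
    g(D=0 | x, c) on exposure plus confounders (denominator); returns the two
    predicted survival probabilities per person-year, clipped into
    [1e-3, 1 - 1e-3].  If no deaths are present both are identically 1 (with a
    warning) so the death factor drops out of the weight.
    """
    import lightgbm as lgb

    spec.validate()
    d = person_years["D"].to_numpy(int)
    n = d.size
    if d.sum() == 0:
        warnings.warn(
            "no deaths in the person-year table; competing-risk factor set to 1",
            stacklevel=2,
        )
        return np.ones(n), np.ones(n)
    survive = (d == 0).astype(int)

    X_num = person_years[[spec.target_exposure]].astype(float)
    X_den = pd.concat(
        [X_num, _design_matrix(person_years, spec.confounder_columns)], axis=1
    )

    def _fit(X: pd.DataFrame, seed: int) -> np.ndarray:
        if spec.gbm_params.n_trees == 0:
            return np.full(n, survive.mean())
        if spec.gbm_params.loss == "bernoulli":
            model = lgb.LGBMClassifier(
                objective="binary", **_lgbm_common(spec.gbm_params, seed)
            )
            model.fit(X, survive)
            return model.predict_proba(X)[:, 1]
        model = lgb.LGBMRegressor(
            objective="regression", **_lgbm_common(spec.gbm_params, seed)
        )
        model.fit(X, survive.astype(float))
        return model.predict(X)

    s_num = np.clip(_fit(X_num, spec.seed + 1), _PROB_CLIP, 1 - _PROB_CLIP)
    s_den = np.clip(_fit(X_den, spec.seed + 2), _PROB_CLIP, 1 - _PROB_CLIP)
    return s_num, s_den


# ---------------------------------------------------------------------------
# stabilized weights
# ---------------------------------------------------------------------------


def stabilized_weights(person_years: pd.DataFrame, spec: DesignSpec) -> WeightSet:
    """Estimate the stabilized IPW of every person-year for ``spec``'s target.

    The four components multiply to the raw weight exactly; optional
    percentile truncation (capping at the configured lower/upper percentiles
    of the raw weights) is applied last.
    """
    spec.validate()
    x = person_years[spec.target_exposure].to_numpy(float)
    _, residuals, r2 = fit_exposure_model(person_years, spec)
    centered = x - x.mean()

    scale_factor = 1.0
    if spec.residual_scale_calibration:
        honest_sd = honest_residual_scale(person_years, spec)
        in_sample_sd = residuals.std()
        if in_sample_sd > 0:
            scale_factor = honest_sd / in_sample_sd
        residuals = residuals * scale_factor

    k_num = kde(centered, spec.kde_params)
    k_den = kde(residuals, spec.kde_params)
    num_density = k_num(centered)
    den_density = k_den(residuals)

    death_num, death_den = fit_death_models(person_years, spec)

    sw_raw = (num_density / den_density) * (death_num / death_den)
    bad = ~np.isfinite(sw_raw) | (sw_raw <= 0)
    if bad.any():
        offenders = person_years.loc[bad, ["person_id", "year"]].head(10)
        raise FloatingPointError(
            f"non-finite or non-positive weights for person-years:\n{offenders}"
        )

    if spec.truncation is not None:
        lo, hi = np.percentile(sw_raw, spec.truncation)
        sw = np.clip(sw_raw, lo, hi)
    else:
        sw = sw_raw.copy()

    components = pd.DataFrame(
        {
            "num_density": num_density,
            "den_density": den_density,
            "death_num": death_num,
            "death_den": death_den,
        }
    )
    diagnostics = {
        "n": int(x.size),
        "mean_weight": float(sw.mean()),
        "mean_weight_raw": float(sw_raw.mean()),
        "max_weight": float(sw.max()),
        "effective_sample_size": effective_sample_size(sw),
        "ess_fraction": effective_sample_size(sw) / x.size,
        "exposure_model_r2": r2,
        "residual_scale_factor": float(scale_factor),
        "bandwidth_num": k_num.bandwidth,
        "bandwidth_den": k_den.bandwidth,
        "truncation": spec.truncation,
        "target_exposure": spec.target_exposure,
        "seed": spec.seed,
    }
    weight_set = WeightSet(
        sw=sw, sw_raw=sw_raw, components=components, diagnostics=diagnostics
    )
    balance = balance_diagnostics(person_years, weight_set, spec)
    diagnostics["balance"] = balance.to_dict("records")
    diagnostics["n_flagged_covariates"] = int(balance["flagged"].sum())
    return weight_set


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------


def _weighted_corr(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    am = a - np.sum(w * a)
    bm = b - np.sum(w * b)
    va = np.sum(w * am**2)
    vb = np.sum(w * bm**2)
    if va <= 0 or vb <= 0:
        return 0.0
    return float(np.sum(w * am * bm) / np.sqrt(va * vb))


def balance_diagnostics(
    person_years: pd.DataFrame,
    weights: WeightSet | np.ndarray,
    spec: DesignSpec,
    flag_threshold: float = 0.1,
) -> pd.DataFrame:
    """Weighted vs unweighted association of each confounder with the target.

    Continuous (and binary) confounders use the Pearson correlation; levels of
    categorical confounders use the standardized mean difference of the level
    indicator between person-years above vs below the weighted median
    exposure.  Covariates whose weighted |association| exceeds
    ``flag_threshold`` are flagged; zero-variance covariates report 0 with a
    degeneracy flag.
    """
    w = weights.sw if isinstance(weights, WeightSet) else np.asarray(weights, float)
    x = person_years[spec.target_exposure].to_numpy(float)
    ones = np.ones_like(w)
    X = _design_matrix(person_years, spec.confounder_columns)

    order = np.argsort(x)
    cum = np.cumsum(w[order])
    median_x = x[order][np.searchsorted(cum, 0.5 * cum[-1])]
    hi = x > median_x

    rows = []
    raw_cols = list(spec.confounder_columns)
    categorical = {
        c
        for c in raw_cols
        if person_years[c].dtype == object or str(person_years[c].dtype) == "category"
    }
    for col in X.columns:
        parent = next((c for c in categorical if col.startswith(c + "_")), None)
        a = X[col].to_numpy(float)
        degenerate = a.var() == 0
        if degenerate:
            unweighted = weighted = 0.0
        elif parent is not None:
            # SMD of the level share between high/low exposure halves
            sd = a.std(ddof=1)

            def _smd(wt: np.ndarray) -> float:
                return float(
                    (np.average(a[hi], weights=wt[hi]) - np.average(a[~hi], weights=wt[~hi]))
                    / sd
                )

            unweighted, weighted = _smd(ones), _smd(w)
        else:
            unweighted = _weighted_corr(a, x, ones)
            weighted = _weighted_corr(a, x, w)
        rows.append(
            {
                "covariate": col,
                "metric": "smd" if parent is not None else "correlation",
                "unweighted": float(unweighted),
                "weighted": float(weighted),
                "flagged": bool((not degenerate) and abs(weighted) > flag_threshold),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)
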