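"""Synthetic open-cohort generator for air-pollution / cancer-incidence analyses.

Emulates the structure of a Medicare-style cohort: an open cohort observed
2000-2016, annual ZIP-level PM2.5 and NO2 concentrations with spatial
heterogeneity and AR(1) temporal autocorrelation, community covariates that can
confound the exposure, individual risk factors, a competing death process, and
a cancer-diagnosis process that is *additive* in six distributed-lag exposure
windows.  The ground-truth coefficients are exported so that the two-stage
IPW pipeline can be tested for parameter recovery.

Probabilities are annual.  Within a calendar year death is evaluated first and
diagnosis only among survivors, so death literally competes with (precludes)
the cancer diagnosis in that year.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._utils import spawn_seed

#: canonical order of the six distributed-lag exposure windows
WINDOW_NAMES = (
    "pm25_lag02",
    "pm25_lag35",
    "pm25_lag610",
    "no2_lag02",
    "no2_lag35",
    "no2_lag610",
)

POLLUTANTS = ("pm25", "no2")

#: (lo, hi) lag bounds in years for each window suffix
WINDOW_LAGS = {"lag02": (0, 2), "lag35": (3, 5), "lag610": (6, 10)}

#: names of the confounder *indicators* recognised by the generating process
CONFOUNDER_KEYS = (
    "female",
    "medicaid",
    "age85",
    "race_black",
    "race_other",
    "comm_smoking",
    "comm_bmi",
    "comm_adi",
)

COMMUNITY_COLUMNS = ("comm_smoking", "comm_bmi", "comm_adi")


@dataclass(frozen=True)
class ExposureParams:
    """Parameters of one pollutant's ZIP-year concentration process.

    The concentration in ZIP z and year t is

        mu_z + trend_per_year * (t - study_start) + e_{z,t}

    where mu_z varies across ZIPs with sd ``spatial_sd`` (plus a shift of
    ``confounding_strength`` per sd of the community confounder) and e follows
    a stationary AR(1) with coefficient ``ar1_coefficient`` and innovation sd
    ``innovation_sd``.  Units are ug/m3 (PM2.5) or ppb (NO2).
    """

    spatial_mean: float
    spatial_sd: float
    ar1_coefficient: float
    innovation_sd: float
    trend_per_year: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.spatial_sd < 0 or self.innovation_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth coefficients of the data-generating process.

    ``beta_windows`` follows :data:`WINDOW_NAMES` order and holds the additive
    annual-risk increment per unit of each lag-window exposure; these are the
    quantities the weighted linear probability model must recover.

    Two optional departures from a globally linear dose-response support
    recovery tests of the secondary analyses: ``beta_low_extra`` adds a
    steeper slope for the first window below ``low_threshold`` (an extra
    ``beta_low_extra * (x - low_threshold)`` while x < threshold), and
    ``beta_modifiers`` adds ``delta * c * x`` interaction terms between named
    confounder indicators and the first window.
    """

    beta0_cancer: float
    beta_windows: tuple[float, float, float, float, float, float]
    gamma_confounders: Mapping[str, float] = field(default_factory=dict)
    death_base: float = 0.025
    death_exposure_coeff: float = 5e-4
    death_confounder_coeffs: Mapping[str, float] = field(default_factory=dict)
    beta_low_extra: float = 0.0
    low_threshold: float | None = None
    beta_modifiers: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.beta_windows) != len(WINDOW_NAMES):
            raise ValueError("beta_windows must have six entries")
        keys = (
            list(self.gamma_confounders)
            + list(self.death_confounder_coeffs)
            + list(self.beta_modifiers)
        )
        for key in keys:
            if key not in CONFOUNDER_KEYS:
                raise ValueError(f"unknown confounder key {key!r}")
        if self.beta_low_extra and self.low_threshold is None:
            raise ValueError("beta_low_extra requires low_threshold")
        if not (0.0 <= self.beta0_cancer <= 1.0 and 0.0 <= self.death_base <= 1.0):
            raise ValueError("baseline probabilities must lie in [0, 1]")


def _default_exposure_params() -> dict[str, ExposureParams]:
    # Means match the observed national annual averages (9.8 ug/m3 PM2.5,
    # 17.3 ppb NO2); spread and persistence give realistic between-ZIP
    # contrasts and within-ZIP year-to-year autocorrelation, with a mild
    # secular decline.
    return {
        "pm25": ExposureParams(9.8, 0.5, 0.5, 1.9, -0.10),
        "no2": ExposureParams(17.3, 2.0, 0.5, 2.4, -0.30),
    }


def _default_truth() -> SimTruth:
    return SimTruth(
        beta0_cancer=1.5e-4,
        beta_windows=(5e-5, 0.0, 0.0, 0.0, 0.0, 0.0),
        gamma_confounders={},
        death_base=0.025,
        death_exposure_coeff=5e-4,
        death_confounder_coeffs={"age85": 0.04},
    )


@dataclass
class SimConfig:
    """Full configuration of the synthetic cohort."""

    n_individuals: int = 50_000
    study_start: int = 2000
    study_end: int = 2016
    n_zips: int = 1500
    exposure_params: Mapping[str, ExposureParams] = field(
        default_factory=_default_exposure_params
    )
    confounding_strength: float = 0.0
    truth: SimTruth = field(default_factory=_default_truth)
    #: probability that the cohort starts at study_start (the rest enter
    #: uniformly in the following years that still allow a 10-year run-in)
    entry_at_start_prob: float = 0.9
    move_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.study_end <= self.study_start + 11:
            raise ValueError("study_end must exceed study_start + 11")
        if self.n_individuals <= 0 or self.n_zips <= 0:
            raise ValueError("n_individuals and n_zips must be positive")
        if not (0.0 <= self.move_prob <= 1.0):
            raise ValueError("move_prob must lie in [0, 1]")
        for p in POLLUTANTS:
            if p not in self.exposure_params:
                raise ValueError(f"missing exposure_params for {p!r}")
            self.exposure_params[p].validate()
        self.truth.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exposure_params"] = {
            k: dataclasses.asdict(v) for k, v in self.exposure_params.items()
        }
        d["truth"] = dataclasses.asdict(self.truth)
        return d


# ---------------------------------------------------------------------------
# community covariates and exposure surface
# ---------------------------------------------------------------------------


def simulate_communities(config: SimConfig) -> pd.DataFrame:
    """ZIP-level community covariates (one row per ZIP).

    ``comm_adi`` (a standardized deprivation index) is the covariate that may
    drive the exposure mean when ``confounding_strength`` is non-zero; it is
    drawn from a centered uniform so that confounder effects on annual risks
    stay bounded.  The other two covariates are standard-normal noise.
    """
    rng = np.random.default_rng(spawn_seed(config.seed, "communities"))
    nz = config.n_zips
    half_width = np.sqrt(3.0)  # centered uniform with unit variance
    return pd.DataFrame(
        {
            "zip": np.arange(nz),
            "comm_smoking": rng.standard_normal(nz),
            "comm_bmi": rng.standard_normal(nz),
            "comm_adi": rng.uniform(-half_width, half_width, nz),
        }
    )


def simulate_exposure_surface(
    config: SimConfig, communities: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate annual ZIP-level concentrations for both pollutants.

    Returns a wide table (zip, year, pm25, no2) covering
    ``study_start - 10 .. study_end`` so that every lag 6-10 window of every
    follow-up year is complete, together with a report of how many values were
    truncated at zero.  Raises if more than 10% of values needed truncation.
    """
    config.validate()
    if communities is None:
        communities = simulate_communities(config)
    rng = np.random.default_rng(spawn_seed(config.seed, "exposure"))
    years = np.arange(config.study_start - 10, config.study_end + 1)
    nz, ny = config.n_zips, years.size
    u = communities["comm_adi"].to_numpy()
    u_centered = u - u.mean()

    report: dict[str, int | float] = {"n_values": int(nz * ny * len(POLLUTANTS))}
    frames = {}
    for pollutant in POLLUTANTS:
        p = config.exposure_params[pollutant]
        mu = (
            p.spatial_mean
            + p.spatial_sd * rng.standard_normal(nz)
            + config.confounding_strength * u_centered
        )
        e = np.empty((nz, ny))
        if p.ar1_coefficient > 0 and p.innovation_sd > 0:
            stat_sd = p.innovation_sd / np.sqrt(1.0 - p.ar1_coefficient**2)
        else:
            stat_sd = p.innovation_sd
        e[:, 0] = rng.normal(0.0, stat_sd, nz)
        for t in range(1, ny):
            e[:, t] = p.ar1_coefficient * e[:, t - 1] + rng.normal(
                0.0, p.innovation_sd, nz
            )
        vals = mu[:, None] + p.trend_per_year * (years - config.study_start)[None, :] + e
        n_trunc = int((vals < 0).sum())
        report[f"truncated_{pollutant}"] = n_trunc
        frames[pollutant] = np.clip(vals, 0.0, None)

    total_trunc = sum(report[f"truncated_{p}"] for p in POLLUTANTS)
    report["truncated_fraction"] = total_trunc / report["n_values"]
    if report["truncated_fraction"] > 0.10:
        raise ValueError(
            f"{report['truncated_fraction']:.1%} of simulated concentrations were "
            "negative and truncated at 0; choose gentler exposure parameters"
        )

    zz, yy = np.meshgrid(np.arange(nz), years, indexing="ij")
    out = pd.DataFrame(
        {
            "zip": zz.ravel(),
            "year": yy.ravel(),
            "pm25": frames["pm25"].ravel(),
            "no2": frames["no2"].ravel(),
        }
    )
    return out, report


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------


def _confounder_matrix(persons: pd.DataFrame, communities: pd.DataFrame) -> pd.DataFrame:
    """Numeric indicator matrix (columns = CONFOUNDER_KEYS) for each person."""
    comm = communities.set_index("zip").loc[persons["zip"].to_numpy()].reset_index()
    return pd.DataFrame(
        {
            "female": (persons["sex"] == "female").astype(float).to_numpy(),
            "medicaid": persons["medicaid"].astype(float).to_numpy(),
            "age85": (persons["age_group"] == "85+").astype(float).to_numpy(),
            "race_black": (persons["race"] == "black").astype(float).to_numpy(),
            "race_other": (persons["race"] == "other").astype(float).to_numpy(),
            "comm_smoking": comm["comm_smoking"].to_numpy(),
            "comm_bmi": comm["comm_bmi"].to_numpy(),
            "comm_adi": comm["comm_adi"].to_numpy(),
        }
    )


def simulate_population(
    config: SimConfig,
    exposures: pd.DataFrame | None = None,
    communities: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate person records (enrollment, events) under the configured truth.

    For each person-year while enrolled, alive, and diagnosis-free:

    * death occurs with probability
      ``death_base + death_exposure_coeff * pm25(zip, year) + sum(coeff * c)``;
    * conditional on surviving the year, a first cancer diagnosis occurs with
      probability ``beta0_cancer + sum(beta_windows * x_windows) + sum(gamma * c)``.

    Probabilities are clipped to [0, 1]; the run errors out if more than 1% of
    person-years required clipping, because that would invalidate recovery of
    the linear truth.  Returns the person table and a truth report (the
    configured coefficients plus realized event counts).
    """
    from .cohort import window_means_by_zip_year  # shared lag-window definition

    config.validate()
    if communities is None:
        communities = simulate_communities(config)
    if exposures is None:
        exposures, _ = simulate_exposure_surface(config, communities)
    rng = np.random.default_rng(spawn_seed(config.seed, "population"))
    n = config.n_individuals
    truth = config.truth

    # --- fixed person attributes -----------------------------------------
    zips = rng.integers(0, config.n_zips, n)
    last_entry = config.study_end - 10
    entry_span = last_entry - config.study_start
    at_start = rng.random(n) < config.entry_at_start_prob
    enroll = np.where(
        at_start,
        config.study_start,
        config.study_start + 1 + rng.integers(0, max(entry_span, 1), n),
    )
    persons = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "sex": np.where(rng.random(n) < 0.62, "female", "male"),
            "race": rng.choice(["white", "black", "other"], n, p=[0.91, 0.053, 0.037]),
            "medicaid": (rng.random(n) < 0.11).astype(int),
            "age_group": np.where(rng.random(n) < 0.15, "85+", "75-84"),
            "enroll_year": enroll,
            "zip": zips,
        }
    )

    conf = _confounder_matrix(persons, communities)
    gamma = np.array([truth.gamma_confounders.get(k, 0.0) for k in CONFOUNDER_KEYS])
    dcoef = np.array(
        [truth.death_confounder_coeffs.get(k, 0.0) for k in CONFOUNDER_KEYS]
    )
    conf_np = conf.to_numpy()
    cancer_conf = conf_np @ gamma
    death_conf = conf_np @ dcoef

    # --- exposure lookups -------------------------------------------------
    windows, zip_index, year_index = window_means_by_zip_year(exposures)
    beta = np.asarray(truth.beta_windows, float)
    zip_pos = zip_index.get_indexer(zips)
    if (zip_pos < 0).any():
        raise ValueError("some persons live in ZIPs absent from the exposure table")
    pm25_current = (
        exposures.pivot(index="zip", columns="year", values="pm25")
        .reindex(index=zip_index, columns=year_index)
        .to_numpy()
    )

    # --- annual event loop (death first, then diagnosis among survivors) --
    alive = np.ones(n, bool)
    cancer_free = np.ones(n, bool)
    death_year = np.full(n, np.nan)
    cancer_year = np.full(n, np.nan)
    n_clipped = 0
    n_person_years = 0

    for year in range(config.study_start, config.study_end + 1):
        t = year_index.get_loc(year)
        active = alive & cancer_free & (enroll <= year)
        if not active.any():
            continue
        idx = np.flatnonzero(active)
        n_person_years += idx.size

        p_death = (
            truth.death_base
            + truth.death_exposure_coeff * pm25_current[zip_pos[idx], t]
            + death_conf[idx]
        )
        x_win = np.column_stack(
            [windows[w][zip_pos[idx], t] for w in WINDOW_NAMES]
        )
        p_cancer = truth.beta0_cancer + x_win @ beta + cancer_conf[idx]
        if truth.low_threshold is not None and truth.beta_low_extra:
            p_cancer = p_cancer + truth.beta_low_extra * np.minimum(
                x_win[:, 0] - truth.low_threshold, 0.0
            )
        if truth.beta_modifiers:
            for key, delta in truth.beta_modifiers.items():
                col = CONFOUNDER_KEYS.index(key)
                p_cancer = p_cancer + delta * conf_np[idx, col] * x_win[:, 0]

        n_clipped += int(((p_death < 0) | (p_death > 1)).sum())
        n_clipped += int(((p_cancer < 0) | (p_cancer > 1)).sum())
        p_death = np.clip(p_death, 0.0, 1.0)
        p_cancer = np.clip(p_cancer, 0.0, 1.0)

        died = rng.random(idx.size) < p_death
        death_year[idx[died]] = year
        alive[idx[died]] = False

        surv = idx[~died]
        diagnosed = rng.random(surv.size) < p_cancer[~died]
        cancer_year[surv[diagnosed]] = year
        cancer_free[surv[diagnosed]] = False

    clip_fraction = n_clipped / max(n_person_years, 1)
    if clip_fraction > 0.01:
        raise ValueError(
            f"{clip_fraction:.2%} of person-years had event probabilities clipped "
            "to [0, 1]; the configured truth is not additive over the realized "
            "covariate range"
        )

    persons["death_year"] = pd.array(
        np.where(np.isnan(death_year), pd.NA, death_year), dtype="Int64"
    )
    persons["cancer_year"] = pd.array(
        np.where(np.isnan(cancer_year), pd.NA, cancer_year), dtype="Int64"
    )

    truth_report = {
        "truth": dataclasses.asdict(truth),
        "confounding_strength": config.confounding_strength,
        "seed": config.seed,
        "realized": {
            "n_persons": int(n),
            "n_deaths": int(persons["death_year"].notna().sum()),
            "n_diagnoses": int(persons["cancer_year"].notna().sum()),
            "person_years_simulated": int(n_person_years),
            "clipped_person_years": int(n_clipped),
            "clipped_fraction": float(clip_fraction),
        },
    }
    return persons, truth_report


def simulate_cohort_data(
    config: SimConfig, out_dir: str | Path | None = None
) -> dict[str, object]:
    """Run the full generator and optionally write the standard CSV/JSON files.

    Outputs ``persons.csv``, ``zip_exposures.csv``, ``zip_covariates.csv`` and
    ``truth.json`` (the ground truth plus realized event counts).
    """
    config.validate()
    communities = simulate_communities(config)
    exposures, exposure_report = simulate_exposure_surface(config, communities)
    persons, truth_report = simulate_population(config, exposures, communities)
    truth_report["exposure"] = exposure_report

    years = np.arange(config.study_start - 10, config.study_end + 1)
    zip_covariates = communities.loc[
        communities.index.repeat(years.size)
    ].reset_index(drop=True)
    zip_covariates.insert(1, "year", np.tile(years, len(communities)))

    tables = {
        "persons": persons,
        "zip_exposures": exposures,
        "zip_covariates": zip_covariates,
        "truth": truth_report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        persons.to_csv(out / "persons.csv", index=False)
        exposures.to_csv(out / "zip_exposures.csv", index=False)
        zip_covariates.to_csv(out / "zip_covariates.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth_report, indent=2))
    return tables


# ---------------------------------------------------------------------------
# named study scenarios
# ---------------------------------------------------------------------------


def scenario_unconfounded(n_individuals: int = 50_000, seed: int = 0) -> SimConfig:
    """True additive effect on one window, no exposure-outcome confounding."""
    return SimConfig(n_individuals=n_individuals, seed=seed)


def scenario_confounded(n_individuals: int = 50_000, seed: int = 0) -> SimConfig:
    """Community deprivation shifts the exposure mean by +1 unit per covariate
    sd and the annual cancer risk by +2e-4 per covariate sd."""
    truth = dataclasses.replace(
        _default_truth(), gamma_confounders={"comm_adi": 2e-4}
    )
    return SimConfig(
        n_individuals=n_individuals,
        confounding_strength=1.0,
        truth=truth,
        seed=seed,
    )


def scenario_death_confounded(n_individuals: int = 50_000, seed: int = 0) -> SimConfig:
    """As :func:`scenario_confounded`, but the same community covariate also
    raises annual mortality, so death differentially censors exposed strata."""
    truth = dataclasses.replace(
        _default_truth(),
        gamma_confounders={"comm_adi": 2e-4},
        death_confounder_coeffs={"age85": 0.04, "comm_adi": 0.015},
    )
    return SimConfig(
        n_individuals=n_individuals,
        confounding_strength=1.0,
        truth=truth,
        seed=seed,
    )
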