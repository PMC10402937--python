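"""Cohort construction: inclusion, censoring, lag-window exposures, person-years.

The analysis unit is the *person-year*: one beneficiary's one calendar year
under observation after a 10-year cancer-free run-in.  Each person-year
carries six moving-average exposures (PM2.5 and NO2 at lag 0-2, lag 3-5 and
lag 6-10 years), the confounder vector, and the death / diagnosis indicators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import COMMUNITY_COLUMNS, POLLUTANTS, WINDOW_LAGS, WINDOW_NAMES

logger = logging.getLogger(__name__)

#: years of cancer-free follow-up required before a person enters the risk set
RUN_IN_YEARS = 10

INDIVIDUAL_COLUMNS = ("sex", "race", "medicaid", "age_group")


@dataclass
class PersonRecord:
    """One beneficiary, as used by the single-person helper API."""

    person_id: int
    sex: str
    race: str
    medicaid: int
    enroll_year: int
    zip_by_year: Mapping[int, int] = field(default_factory=dict)
    death_year: int | None = None
    cancer_year: int | None = None

    def zip_in(self, year: int) -> int:
        if year in self.zip_by_year:
            return self.zip_by_year[year]
        # constant residence: a single entry keyed by enrollment year
        if len(set(self.zip_by_year.values())) == 1:
            return next(iter(self.zip_by_year.values()))
        raise KeyError(f"no residence ZIP recorded for year {year}")


# ---------------------------------------------------------------------------
# lag windows
# ---------------------------------------------------------------------------


def window_means_by_zip_year(
    zip_exposures: pd.DataFrame,
) -> tuple[dict[str, np.ndarray], pd.Index, pd.Index]:
    """Moving-average exposure matrices for all six windows.

    Returns ``(windows, zip_index, year_index)`` where ``windows[name]`` is a
    (n_zips, n_years) array whose entry (z, t) is the mean over the window's
    lag years; entries whose window is not fully covered are NaN.  Lag w at
    year t uses years ``t - hi .. t - lo`` inclusive.
    """
    years = np.arange(zip_exposures["year"].min(), zip_exposures["year"].max() + 1)
    windows: dict[str, np.ndarray] = {}
    zip_index = year_index = None
    for pollutant in POLLUTANTS:
        wide = zip_exposures.pivot(index="zip", columns="year", values=pollutant)
        wide = wide.reindex(columns=years)
        zip_index, year_index = wide.index, wide.columns
        vals = wide.to_numpy()
        # prefix sums with a leading zero column; NaNs propagate so that any
        # missing zip-year poisons every window that needs it
        cs = np.concatenate(
            [np.zeros((vals.shape[0], 1)), np.cumsum(vals, axis=1)], axis=1
        )
        for suffix, (lo, hi) in WINDOW_LAGS.items():
            width = hi - lo + 1
            out = np.full_like(vals, np.nan)
            # window for column t covers columns t-hi .. t-lo
            t = np.arange(hi, vals.shape[1])
            out[:, t] = (cs[:, t - lo + 1] - cs[:, t - hi]) / width
            windows[f"{pollutant}_{suffix}"] = out
    return windows, zip_index, year_index


def build_lag_exposures(
    zip_exposures: pd.DataFrame, person: PersonRecord | Mapping, year: int
) -> dict[str, float]:
    """Six lag-window exposures for one person in one index year.

    Uses the ZIP of residence in each lagged year (relevant only when the
    residence history records moves).  Raises if any required zip-year value
    is missing -- there is no silent imputation.
    """
    if isinstance(person, Mapping) and not isinstance(person, PersonRecord):
        person = PersonRecord(
            person_id=person.get("person_id", -1),
            sex=person.get("sex", ""),
            race=person.get("race", ""),
            medicaid=person.get("medicaid", 0),
            enroll_year=person.get("enroll_year", year),
            zip_by_year=person.get("zip_by_year") or {year: person["zip"]},
        )
    lookup = zip_exposures.set_index(["zip", "year"])
    out: dict[str, float] = {}
    for pollutant in POLLUTANTS:
        for suffix, (lo, hi) in WINDOW_LAGS.items():
            vals = []
            for lag in range(lo, hi + 1):
                y = year - lag
                z = person.zip_in(y)
                try:
                    vals.append(float(lookup.at[(z, y), pollutant]))
                except KeyError:
                    raise KeyError(
                        f"missing exposure for zip={z}, year={y} "
                        f"(person {person.person_id}, window {pollutant}_{suffix})"
                    ) from None
            out[f"{pollutant}_{suffix}"] = float(np.mean(vals))
    return out


# ---------------------------------------------------------------------------
# inclusion and censoring
# ---------------------------------------------------------------------------


def apply_inclusion_and_censor(
    persons: pd.DataFrame, study_end: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the 10-year cancer-free inclusion rule and censoring.

    A person is included iff (a) their enrollment year + 10 does not pass the
    end of study, (b) no cancer diagnosis and (c) no death occurred strictly
    before enrollment + 10.  Included persons contribute person-years from
    ``enroll_year + 10`` through the first of cancer diagnosis, death, or the
    end of study.  Persons flagged ``eligible == 0`` (e.g. without continuous
    fee-for-service enrollment) are dropped before the inclusion rules.

    Returns ``(included, exclusions)``.  ``included`` adds ``follow_start``
    and ``censor_year``; ``exclusions`` records person_id, reason
    (``ineligible | early_cancer | early_death | insufficient_followup``) and
    the person-years the excluded person spent under observation before their
    own censoring event (needed for the attributable-case denominator).
    """
    df = persons.copy()
    for col in ("death_year", "cancer_year"):
        if col not in df:
            df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
        df[col] = df[col].astype("Int64")
    bad_death = df["death_year"].notna() & (df["death_year"] < df["enroll_year"])
    bad_cancer = df["cancer_year"].notna() & (df["cancer_year"] < df["enroll_year"])
    if bool(bad_death.any() or bad_cancer.any()):
        raise ValueError("event year precedes enrollment year for some persons")

    follow_start = df["enroll_year"] + RUN_IN_YEARS
    event_year = df[["cancer_year", "death_year"]].min(axis=1)
    own_censor = event_year.fillna(study_end).clip(upper=study_end)
    observed_years = (own_censor - df["enroll_year"] + 1).astype(int)

    if "eligible" in df:
        ineligible = df["eligible"].fillna(1).astype(int) == 0
    else:
        ineligible = pd.Series(False, index=df.index)
    early_cancer = df["cancer_year"].notna() & (df["cancer_year"] < follow_start)
    early_death = df["death_year"].notna() & (df["death_year"] < follow_start)
    insufficient = follow_start > study_end

    reason = pd.Series(pd.NA, index=df.index, dtype="string")
    # precedence: eligibility, then early events, then administrative end
    reason[insufficient] = "insufficient_followup"
    reason[early_death] = "early_death"
    reason[early_cancer] = "early_cancer"
    reason[ineligible] = "ineligible"
    excluded_mask = reason.notna()

    exclusions = pd.DataFrame(
        {
            "person_id": df.loc[excluded_mask, "person_id"].to_numpy(),
            "reason": reason[excluded_mask].to_numpy(),
            "person_years": observed_years[excluded_mask].to_numpy(),
        }
    )

    included = df.loc[~excluded_mask].copy()
    included["follow_start"] = follow_start[~excluded_mask]
    included["censor_year"] = own_censor[~excluded_mask].astype(int)
    return included.reset_index(drop=True), exclusions.reset_index(drop=True)


def assemble_person_years(
    included: pd.DataFrame,
    zip_exposures: pd.DataFrame,
    zip_covariates: pd.DataFrame,
    residence: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Expand included persons into the person-year analysis table.

    One row per included person per follow-up year up to censoring, with the
    six lag-window exposures (from the ZIP of residence in each year),
    individual covariates, that zip-year's community covariates, and the
    Y (first cancer diagnosis) / D (death) indicators in the final row.
    When the diagnosis and death fall in the same year the diagnosis takes
    precedence (it was observed first).
    """
    if included.empty:
        raise ValueError("no included persons")
    n_years = (included["censor_year"] - included["follow_start"] + 1).to_numpy()
    if (n_years <= 0).any():
        raise ValueError("censoring precedes follow-up start for some persons")
    rep = np.repeat(included.index.to_numpy(), n_years)
    py = included.loc[rep].reset_index(drop=True)
    offsets = np.concatenate([np.arange(k) for k in n_years])
    py["year"] = (py["follow_start"] + offsets).astype(int)

    # residence in the index year (and, through the window matrices below,
    # in each lagged year) -- defaults to the constant enrollment ZIP
    if residence is not None:
        res = residence.set_index(["person_id", "year"])["zip"]
        key = pd.MultiIndex.from_arrays([py["person_id"], py["year"]])
        moved = res.reindex(key)
        py["zip"] = np.where(moved.notna(), moved.to_numpy(), py["zip"].to_numpy())

    cancer = py["cancer_year"].astype("Int64")
    death = py["death_year"].astype("Int64")
    py["Y"] = ((cancer == py["year"])).fillna(False).astype(int)
    py["D"] = (
        (death == py["year"]) & ~((cancer.notna()) & (cancer <= death))
    ).fillna(False).astype(int)

    windows, zip_index, year_index = window_means_by_zip_year(zip_exposures)
    zpos = zip_index.get_indexer(py["zip"].to_numpy())
    ypos = year_index.get_indexer(py["year"].to_numpy())
    if (zpos < 0).any() or (ypos < 0).any():
        bad = py.loc[(zpos < 0) | (ypos < 0), ["person_id", "year", "zip"]].head()
        raise KeyError(f"exposure table does not cover some person-years:\n{bad}")
    if residence is not None:
        # with mobility the lag windows must follow the residence history
        py_windows = _windows_with_mobility(py, residence, zip_exposures)
        for name in WINDOW_NAMES:
            py[name] = py_windows[name]
    else:
        for name in WINDOW_NAMES:
            py[name] = windows[name][zpos, ypos]
    missing = py[list(WINDOW_NAMES)].isna().any(axis=1)
    if missing.any():
        bad = py.loc[missing, ["person_id", "year", "zip"]].head()
        raise KeyError(f"incomplete lag-window exposure for some person-years:\n{bad}")

    comm = zip_covariates.set_index(["zip", "year"])[list(COMMUNITY_COLUMNS)]
    key = pd.MultiIndex.from_arrays([py["zip"], py["year"]])
    comm_rows = comm.reindex(key)
    if comm_rows.isna().any(axis=None):
        raise KeyError("community covariates missing for some zip-years")
    for col in COMMUNITY_COLUMNS:
        py[col] = comm_rows[col].to_numpy()

    cols = (
        ["person_id", "year", "zip"]
        + list(WINDOW_NAMES)
        + list(INDIVIDUAL_COLUMNS)
        + list(COMMUNITY_COLUMNS)
        + ["D", "Y"]
    )
    return py[cols]


def _windows_with_mobility(
    py: pd.DataFrame, residence: pd.DataFrame, zip_exposures: pd.DataFrame
) -> pd.DataFrame:
    """Lag windows that follow each person's ZIP in every lagged year."""
    res = residence.set_index(["person_id", "year"])["zip"]
    lookup = zip_exposures.set_index(["zip", "year"])
    default_zip = py["zip"].to_numpy()
    out = {name: np.empty(len(py)) for name in WINDOW_NAMES}
    pid = py["person_id"].to_numpy()
    year = py["year"].to_numpy()
    for pollutant in POLLUTANTS:
        series = lookup[pollutant]
        for suffix, (lo, hi) in WINDOW_LAGS.items():
            acc = np.zeros(len(py))
            for lag in range(lo, hi + 1):
                y = year - lag
                key = pd.MultiIndex.from_arrays([pid, y])
                z = res.reindex(key).to_numpy()
                z = np.where(pd.notna(z), z, default_zip).astype(int)
                vals = series.reindex(
                    pd.MultiIndex.from_arrays([z, y])
                ).to_numpy()
                acc += vals
            out[f"{pollutant}_{suffix}"] = acc / (hi - lo + 1)
    return pd.DataFrame(out)


def restrict_by_exposure(
    person_years: pd.DataFrame, pollutant: str, threshold: float
) -> pd.DataFrame:
    """Keep person-years whose three lag windows of ``pollutant`` are all
    strictly below ``threshold``; the other pollutant is not filtered on."""
    if pollutant not in POLLUTANTS:
        raise ValueError(f"unknown pollutant {pollutant!r}; expected one of {POLLUTANTS}")
    cols = [f"{pollutant}_{suffix}" for suffix in WINDOW_LAGS]
    mask = (person_years[cols] < threshold).all(axis=1)
    return person_years.loc[mask].reset_index(drop=True)


def person_year_totals(
    person_years: pd.DataFrame, exclusions: pd.DataFrame | None = None
) -> dict[str, int]:
    """Denominators for the attributable-case conversion.

    ``n_analysis`` counts the analysis person-years; ``n_total`` additionally
    includes the observation years of persons excluded during the run-in
    (early cancer/death or administrative end), mirroring a denominator that
    covers every beneficiary-year under observation.
    """
    n_analysis = int(len(person_years))
    n_excluded = int(exclusions["person_years"].sum()) if exclusions is not None else 0
    return {
        "n_analysis": n_analysis,
        "n_excluded": n_excluded,
        "n_total": n_analysis + n_excluded,
    }


# ---------------------------------------------------------------------------
# grid-to-ZIP aggregation (optional spatial input path)
# ---------------------------------------------------------------------------


def aggregate_grid_to_zip(
    grids: pd.DataFrame, zip_geometries: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate grid-cell predictions to ZIP level.

    Polygon ZIPs get the unweighted mean of the values at grid centroids that
    fall inside the polygon; point ZIPs (apartment buildings, post offices...)
    get the value at the nearest grid centroid.  A polygon that contains no
    centroid falls back to nearest-grid with a logged warning.

    ``grids`` needs columns x, y, year, value and optionally pollutant;
    ``zip_geometries`` needs columns zip, geometry (shapely objects or WKT).
    """
    import shapely
    from shapely import wkt as shapely_wkt

    if grids.empty:
        raise ValueError("empty grid table")
    geoms = {}
    for _, row in zip_geometries.iterrows():
        geom = row["geometry"]
        if isinstance(geom, str):
            geom = shapely_wkt.loads(geom)
        if geom is None or geom.is_empty:
            raise ValueError(f"zip {row['zip']} has no geometry")
        if geom.geom_type == "Polygon" and not geom.is_valid:
            raise ValueError(f"zip {row['zip']} polygon is not simple/valid")
        geoms[row["zip"]] = geom

    group_cols = ["year"] + (["pollutant"] if "pollutant" in grids else [])
    records = []
    for keys, grp in grids.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()
        v = grp["value"].to_numpy()
        for z, geom in geoms.items():
            if geom.geom_type == "Polygon":
                inside = shapely.contains_xy(geom, x, y)
                if inside.any():
                    val = float(v[inside].mean())
                else:
                    logger.warning(
                        "zip %s polygon contains no grid centroid; "
                        "falling back to nearest grid",
                        z,
                    )
                    val = float(v[np.argmin((x - geom.centroid.x) ** 2 + (y - geom.centroid.y) ** 2)])
            else:  # point ZIP
                val = float(v[np.argmin((x - geom.x) ** 2 + (y - geom.y) ** 2)])
            records.append(dict(zip(["zip"] + group_cols, [z, *keys]), value=val))
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------


def read_cohort_data(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read the generator's CSV outputs (or user files with the same schemas)."""
    d = Path(directory)
    out = {
        "persons": pd.read_csv(d / "persons.csv"),
        "zip_exposures": pd.read_csv(d / "zip_exposures.csv"),
        "zip_covariates": pd.read_csv(d / "zip_covariates.csv"),
    }
    for col in ("death_year", "cancer_year"):
        out["persons"][col] = out["persons"][col].astype("Int64")
    return out


def build_cohort(
    persons: pd.DataFrame,
    zip_exposures: pd.DataFrame,
    zip_covariates: pd.DataFrame,
    study_end: int,
    residence: pd.DataFrame | None = None,
) -> dict[str, object]:
    """Convenience wrapper: inclusion + censoring + person-year assembly."""
    included, exclusions = apply_inclusion_and_censor(persons, study_end)
    person_years = assemble_person_years(
        included, zip_exposures, zip_covariates, residence=residence
    )
    totals = person_year_totals(person_years, exclusions)
    return {
        "person_years": person_years,
        "exclusions": exclusions,
        "included": included,
        "totals": totals,
    }
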