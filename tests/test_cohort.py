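"""Cohort construction: inclusion, censoring, lag windows, grid aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from airrisk.cohort import (
    PersonRecord,
    aggregate_grid_to_zip,
    apply_inclusion_and_censor,
    assemble_person_years,
    build_lag_exposures,
    person_year_totals,
    restrict_by_exposure,
    window_means_by_zip_year,
)

# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _persons(rows) -> pd.DataFrame:
    df = pd.DataFrame(
        rows,
        columns=["person_id", "enroll_year", "zip", "death_year", "cancer_year"],
    )
    df["sex"] = "female"
    df["race"] = "white"
    df["medicaid"] = 0
    df["age_group"] = "75-84"
    for col in ("death_year", "cancer_year"):
        df[col] = df[col].astype("Int64")
    return df


def _exposures(zips=(0,), years=range(1990, 2017), pm25=10.0, no2=20.0):
    rows = [(z, y, pm25, no2) for z in zips for y in years]
    return pd.DataFrame(rows, columns=["zip", "year", "pm25", "no2"])


def _covariates(zips=(0,), years=range(1990, 2017)):
    rows = [(z, y, 0.1, -0.2, 0.3) for z in zips for y in years]
    return pd.DataFrame(
        rows, columns=["zip", "year", "comm_smoking", "comm_bmi", "comm_adi"]
    )


# ---------------------------------------------------------------------------
# inclusion and censoring
# ---------------------------------------------------------------------------


class TestInclusion:
    def test_cancer_during_run_in_excludes(self):
        persons = _persons([(1, 2000, 0, None, 2007)])
        included, excl = apply_inclusion_and_censor(persons, 2016)
        assert included.empty
        assert list(excl["reason"]) == ["early_cancer"]
        assert list(excl["person_years"]) == [8]  # 2000..2007

    def test_death_during_run_in_excludes(self):
        persons = _persons([(1, 2000, 0, 2004, None)])
        _, excl = apply_inclusion_and_censor(persons, 2016)
        assert list(excl["reason"]) == ["early_death"]
        assert list(excl["person_years"]) == [5]

    def test_follow_up_diagnosis_included_with_py_2010_2013(self):
        persons = _persons([(1, 2000, 0, None, 2013)])
        included, excl = apply_inclusion_and_censor(persons, 2016)
        assert excl.empty
        assert included.loc[0, "follow_start"] == 2010
        assert included.loc[0, "censor_year"] == 2013
        py = assemble_person_years(included, _exposures(), _covariates())
        assert list(py["year"]) == [2010, 2011, 2012, 2013]
        assert list(py["Y"]) == [0, 0, 0, 1]
        assert list(py["D"]) == [0, 0, 0, 0]

    def test_late_enrollment_insufficient_followup(self):
        persons = _persons([(1, 2008, 0, None, None)])
        _, excl = apply_inclusion_and_censor(persons, 2016)
        assert list(excl["reason"]) == ["insufficient_followup"]

    def test_death_without_diagnosis_marks_final_row(self):
        persons = _persons([(1, 2000, 0, 2011, None)])
        included, _ = apply_inclusion_and_censor(persons, 2016)
        py = assemble_person_years(included, _exposures(), _covariates())
        assert list(py["year"]) == [2010, 2011]
        assert list(py["Y"]) == [0, 0]
        assert list(py["D"]) == [0, 1]

    def test_ineligible_flag_filters_before_rules(self):
        persons = _persons([(1, 2000, 0, None, None), (2, 2000, 0, None, None)])
        persons["eligible"] = [0, 1]
        included, excl = apply_inclusion_and_censor(persons, 2016)
        assert list(included["person_id"]) == [2]
        assert list(excl["reason"]) == ["ineligible"]

    def test_event_before_enrollment_rejected(self):
        persons = _persons([(1, 2005, 0, 2003, None)])
        with pytest.raises(ValueError, match="precedes enrollment"):
            apply_inclusion_and_censor(persons, 2016)

    def test_person_year_conservation(self, small_cohort):
        """Included follow-up years + run-in years + excluded observation
        years account for every year under observation."""
        t = small_cohort["tables"]
        persons = t["persons"]
        event = persons[["cancer_year", "death_year"]].min(axis=1)
        own_censor = event.fillna(2016).clip(upper=2016)
        total_observed = int((own_censor - persons["enroll_year"] + 1).sum())

        included = small_cohort["included"]
        run_in = 10 * len(included)
        totals = person_year_totals(
            small_cohort["person_years"], small_cohort["exclusions"]
        )
        assert totals["n_analysis"] + run_in + totals["n_excluded"] == total_observed

    def test_no_rows_after_event(self, small_py):
        last = small_py.groupby("person_id").tail(1)
        events = small_py.groupby("person_id")[["Y", "D"]].sum()
        assert events.max().max() <= 1
        # any Y or D must sit in the final person-year
        flagged = small_py.loc[(small_py["Y"] == 1) | (small_py["D"] == 1)]
        assert flagged.set_index(["person_id", "year"]).index.isin(
            last.set_index(["person_id", "year"]).index
        ).all()

    def test_sum_y_equals_included_diagnoses(self, small_cohort):
        included = small_cohort["included"]
        n_diag = int(included["cancer_year"].notna().sum())
        assert int(small_cohort["person_years"]["Y"].sum()) == n_diag


# ---------------------------------------------------------------------------
# lag windows
# ---------------------------------------------------------------------------


class TestLagWindows:
    def test_constant_series_gives_constant_windows(self):
        person = PersonRecord(1, "female", "white", 0, 2000, {2000: 0})
        out = build_lag_exposures(_exposures(pm25=7.7, no2=13.3), person, 2012)
        for k, v in out.items():
            assert v == pytest.approx(7.7 if k.startswith("pm25") else 13.3)

    def test_linear_series_window_means(self):
        # series value = year - 2006 over 2006..2016; windows at t=2016
        rows = [(0, y, float(y - 2006), 1.0) for y in range(2006, 2017)]
        exposures = pd.DataFrame(rows, columns=["zip", "year", "pm25", "no2"])
        person = PersonRecord(1, "female", "white", 0, 2006, {2006: 0})
        out = build_lag_exposures(exposures, person, 2016)
        assert out["pm25_lag02"] == pytest.approx(9.0)
        assert out["pm25_lag35"] == pytest.approx(6.0)
        assert out["pm25_lag610"] == pytest.approx(2.0)

    def test_missing_year_raises_with_context(self):
        exposures = _exposures(years=range(2000, 2017))  # lacks pre-2000
        person = PersonRecord(1, "female", "white", 0, 2000, {2000: 0})
        with pytest.raises(KeyError, match="zip=0, year=1999"):
            build_lag_exposures(exposures, person, 2009)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 50), min_size=11, max_size=11))
    def test_window_weighted_mean_identity(self, series):
        """(3*lag02 + 3*lag35 + 5*lag610)/11 equals the 11-year mean."""
        rows = [(0, 2000 + i, v, 1.0) for i, v in enumerate(series)]
        exposures = pd.DataFrame(rows, columns=["zip", "year", "pm25", "no2"])
        person = PersonRecord(1, "female", "white", 0, 2000, {2000: 0})
        out = build_lag_exposures(exposures, person, 2010)
        combined = (
            3 * out["pm25_lag02"] + 3 * out["pm25_lag35"] + 5 * out["pm25_lag610"]
        ) / 11
        assert combined == pytest.approx(np.mean(series), rel=1e-12, abs=1e-12)

    def test_bulk_windows_match_single_person_path(self, small_tables):
        exposures = small_tables["zip_exposures"]
        windows, zips, years = window_means_by_zip_year(exposures)
        z, y = int(zips[3]), int(years[15])
        person = PersonRecord(1, "female", "white", 0, y - 10, {y - 10: z})
        single = build_lag_exposures(exposures, person, y)
        for name, mat in windows.items():
            assert mat[3, 15] == pytest.approx(single[name], rel=1e-12)

    def test_mobility_uses_zip_of_each_lagged_year(self):
        # zip 0 has pm25=10, zip 1 has pm25=20; move 0 -> 1 in 2014
        exposures = pd.concat(
            [_exposures(zips=(0,), pm25=10.0), _exposures(zips=(1,), pm25=20.0)]
        ).reset_index(drop=True)
        covariates = pd.concat(
            [_covariates(zips=(0,)), _covariates(zips=(1,))]
        ).reset_index(drop=True)
        persons = _persons([(1, 2004, 0, None, None)])
        residence = pd.DataFrame(
            {"person_id": 1, "year": range(2004, 2017),
             "zip": [0] * 10 + [1] * 3}
        )
        included, _ = apply_inclusion_and_censor(persons, 2016)
        py = assemble_person_years(included, exposures, covariates, residence)
        row_2016 = py.loc[py["year"] == 2016].iloc[0]
        # 2016 lag 0-2 covers 2014..2016, all in zip 1
        assert row_2016["pm25_lag02"] == pytest.approx(20.0)
        # lag 3-5 covers 2011..2013, all in zip 0
        assert row_2016["pm25_lag35"] == pytest.approx(10.0)
        row_2014 = py.loc[py["year"] == 2014].iloc[0]
        assert row_2014["pm25_lag02"] == pytest.approx((20 + 10 + 10) / 3)


# ---------------------------------------------------------------------------
# exposure restriction
# ---------------------------------------------------------------------------


class TestRestriction:
    def _py(self, windows_pm25):
        df = pd.DataFrame([windows_pm25], columns=["pm25_lag02", "pm25_lag35", "pm25_lag610"])
        for c in ("no2_lag02", "no2_lag35", "no2_lag610"):
            df[c] = 99.0
        return df

    def test_all_below_kept(self):
        assert len(restrict_by_exposure(self._py((9.9, 9.9, 9.9)), "pm25", 10.0)) == 1

    def test_boundary_is_strict(self):
        assert len(restrict_by_exposure(self._py((9.9, 10.0, 9.9)), "pm25", 10.0)) == 0

    def test_infinite_threshold_is_noop(self, small_py):
        out = restrict_by_exposure(small_py, "pm25", np.inf)
        assert len(out) == len(small_py)

    def test_other_pollutant_not_filtered(self):
        # no2 windows are 99 but the pm25 restriction ignores them
        assert len(restrict_by_exposure(self._py((1.0, 1.0, 1.0)), "pm25", 10.0)) == 1

    def test_unknown_pollutant_rejected(self, small_py):
        with pytest.raises(ValueError, match="unknown pollutant"):
            restrict_by_exposure(small_py, "ozone", 10.0)


# ---------------------------------------------------------------------------
# grid-to-ZIP aggregation
# ---------------------------------------------------------------------------


def _square(x0, y0, side):
    return (
        f"POLYGON (({x0} {y0}, {x0 + side} {y0}, "
        f"{x0 + side} {y0 + side}, {x0} {y0 + side}, {x0} {y0}))"
    )


class TestGridAggregation:
    def test_polygon_mean_of_contained_centroids(self):
        grids = pd.DataFrame(
            {"x": [0.2, 0.5, 0.8, 5.0], "y": [0.5, 0.5, 0.5, 5.0],
             "year": 2000, "value": [8.0, 10.0, 12.0, 99.0]}
        )
        zips = pd.DataFrame({"zip": ["A"], "geometry": [_square(0, 0, 1)]})
        out = aggregate_grid_to_zip(grids, zips)
        assert out.loc[0, "value"] == pytest.approx(10.0)

    def test_point_zip_gets_nearest_grid(self):
        grids = pd.DataFrame(
            {"x": [1.0, 3.0], "y": [0.0, 0.0], "year": 2000, "value": [5.0, 9.0]}
        )
        zips = pd.DataFrame({"zip": ["P"], "geometry": ["POINT (0 0)"]})
        out = aggregate_grid_to_zip(grids, zips)
        assert out.loc[0, "value"] == pytest.approx(5.0)

    def test_empty_polygon_falls_back_to_nearest(self, caplog):
        grids = pd.DataFrame(
            {"x": [5.0], "y": [5.0], "year": 2000, "value": [7.0]}
        )
        zips = pd.DataFrame({"zip": ["A"], "geometry": [_square(0, 0, 1)]})
        with caplog.at_level("WARNING"):
            out = aggregate_grid_to_zip(grids, zips)
        assert out.loc[0, "value"] == pytest.approx(7.0)
        assert "no grid centroid" in caplog.text

    def test_empty_grid_rejected(self):
        zips = pd.DataFrame({"zip": ["A"], "geometry": [_square(0, 0, 1)]})
        with pytest.raises(ValueError, match="empty grid"):
            aggregate_grid_to_zip(pd.DataFrame(columns=["x", "y", "year", "value"]), zips)

    def test_matches_brute_force_oracle_on_random_rectangles(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = rng.integers(50, 200)
            grids = pd.DataFrame(
                {"x": rng.uniform(0, 10, n), "y": rng.uniform(0, 10, n),
                 "year": 2000, "value": rng.normal(size=n)}
            )
            rects, geoms = [], []
            for k in range(5):
                x0, y0 = rng.uniform(0, 7, 2)
                w, h = rng.uniform(1, 3, 2)
                rects.append((x0, y0, x0 + w, y0 + h))
                geoms.append(_square(0, 0, 1))  # replaced below
            zips = pd.DataFrame(
                {"zip": [f"Z{k}" for k in range(5)],
                 "geometry": [
                     f"POLYGON (({a} {b}, {c} {b}, {c} {d}, {a} {d}, {a} {b}))"
                     for a, b, c, d in rects
                 ]}
            )
            out = aggregate_grid_to_zip(grids, zips).set_index("zip")["value"]
            for k, (a, b, c, d) in enumerate(rects):
                inside = (
                    (grids["x"] > a) & (grids["x"] < c)
                    & (grids["y"] > b) & (grids["y"] < d)
                )
                if inside.any():
                    expected = grids.loc[inside, "value"].mean()
                    assert out[f"Z{k}"] == pytest.approx(expected, rel=1e-12)
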