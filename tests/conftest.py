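"""Shared fixtures: small synthetic cohorts reused across test modules."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from airrisk.cohort import build_cohort
from airrisk.simulate import (
    SimConfig,
    scenario_confounded,
    simulate_cohort_data,
)


@pytest.fixture(scope="session")
def small_tables() -> dict:
    """A small unconfounded cohort (fast; ~20k person-years)."""
    config = SimConfig(n_individuals=5_000, n_zips=300, seed=42)
    return simulate_cohort_data(config)


@pytest.fixture(scope="session")
def small_cohort(small_tables) -> dict:
    t = small_tables
    built = build_cohort(
        t["persons"], t["zip_exposures"], t["zip_covariates"], study_end=2016
    )
    built["tables"] = t
    return built


@pytest.fixture(scope="session")
def small_py(small_cohort) -> pd.DataFrame:
    return small_cohort["person_years"]


@pytest.fixture(scope="session")
def medium_confounded_cohort() -> dict:
    """A confounded cohort big enough for weight/fit behavior (~85k p-y)."""
    config = dataclasses.replace(scenario_confounded(20_000, seed=7), n_zips=800)
    t = simulate_cohort_data(config)
    built = build_cohort(
        t["persons"], t["zip_exposures"], t["zip_covariates"], study_end=2016
    )
    built["tables"] = t
    built["config"] = config
    return built
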