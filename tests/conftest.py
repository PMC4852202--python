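"""Shared fixtures: a small synthetic survey, fitted bundles, and a region.

Session scope amortizes the cost of model fitting across test modules;
all randomness is seeded so the suite is deterministic.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from atpa.pipeline import fit_all
from atpa.population_builder import prepare_block_groups, smooth_labor_force
from atpa.survey_data import stratify
from atpa.synthetic_data import (
    RegionConfig, default_truth, generate_region, generate_survey,
)


@pytest.fixture(scope="session")
def truth():
    return default_truth(n_persons=8000)


@pytest.fixture(scope="session")
def survey(truth):
    return generate_survey(truth, seed=11)


@pytest.fixture(scope="session")
def strata(survey):
    persons, _ = survey
    s = stratify(persons)
    return {"workers": s["working_adults"], "nonworkers": s["nonworking_adults"]}


@pytest.fixture(scope="session")
def bundles(strata, survey):
    _, trips = survey
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_all(strata, trips)


@pytest.fixture(scope="session")
def region():
    return generate_region(
        RegionConfig(n_counties=2, tracts_per_county=2, bgs_per_tract=4),
        seed=7,
    )


@pytest.fixture(scope="session")
def resolved_block_groups(region):
    bg, _ = prepare_block_groups(region)
    return bg


@pytest.fixture(scope="session")
def participation(region):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return smooth_labor_force(region.labor_force)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_persons(n=6, **overrides):
    """Minimal hand-buildable person table for cleaning tests."""
    base = pd.DataFrame({
        "person_id": np.arange(n),
        "household_id": np.arange(n),
        "age": 40,
        "sex": "female",
        "race_ethnicity": "nh_white",
        "education": "college",
        "worker": True,
        "commute_mode": "private_vehicle",
        "time_to_work": 20.0,
        "medical_condition": False,
        "proxy_interview": False,
        "out_of_town": False,
        "travel_day": "monday",
        "weekend": False,
        "season": "winter",
        "heavy_rail_msa": False,
        "state_id": "s1",
        "division_id": "d0",
        "region_id": "r0",
        "pop_density_k": 2.0,
        "pct_rental": 30.0,
        "survey_weight": 1.0,
    })
    for col, vals in overrides.items():
        base[col] = vals
    return base


def make_trips(rows):
    """Trip table from (person_id, mode, purpose, duration) tuples."""
    return pd.DataFrame(
        rows, columns=["person_id", "mode", "purpose", "duration"]
    ).assign(travel_day="monday")
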