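"""Shared fixtures: small programmatic cohorts and simulation configs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import twinpath as tp


@pytest.fixture
def schema() -> tp.VariableSchema:
    return tp.VariableSchema(traits=("cd", "cs"), times=(1, 2), instrument="pgs")


@pytest.fixture
def small_cohort(schema) -> tp.TwinCohort:
    """Ten hand-written pairs with a sprinkling of missing values."""
    rng = np.random.default_rng(17)
    n = 10
    data = {"pair_id": [f"p{i:02d}" for i in range(n)],
            "zygosity": ["MZ"] * 5 + ["DZ"] * 5}
    for col in schema.numeric_columns():
        data[col] = np.round(rng.normal(size=n), 3)
    data["sex_1"] = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
    data["sex_2"] = [0, 1, 0, 1, 0, 0, 1, 1, 0, 1]
    df = pd.DataFrame(data)
    df.loc[2, "cd_t1_1"] = np.nan
    df.loc[7, "cs_t2_2"] = np.nan
    df.loc[4, "pgs_1"] = np.nan
    return tp.TwinCohort(df, schema)


@pytest.fixture
def quiet_config() -> tp.SimConfig:
    """Structural simulation without covariate effects or missingness."""
    return dataclasses.replace(
        tp.SimConfig(),
        sex_effect=0.0,
        age_effect=0.0,
        missing_rate=0.0,
        n_mz=1000,
        n_dz=1000,
        seed=99,
    )
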