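"""Shared synthetic configurations and panels for the test suite.

Everything is generated programmatically at test time; panels are kept small
except where a test needs the bundled calibrated study configuration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heatrhythm.estimator import DEFAULT_COVARIATES
from heatrhythm.synth import (
    ClimateConfig,
    NoiseConfig,
    ProfileConfig,
    SyntheticConfig,
    generate_panel,
)


def zero_effects() -> dict[str, float]:
    return {
        lab: 0.0
        for lab in ["<0", "0-5", "5-10", "10-15", "15-20", "20-25", "25-30",
                    "30-35", ">35"]
    }


@pytest.fixture(scope="session")
def null_config() -> SyntheticConfig:
    """Zero temperature effects, no redistribution, varying climate."""
    return SyntheticConfig(
        n_cities=12,
        parks_per_city=1,
        start_date="2017-03-01",
        n_days=40,
        seed=0,
        bin_effects=zero_effects(),
        covariate_effects={k: 0.0 for k in DEFAULT_COVARIATES},
        fe_scales={"park": 0.3, "hour": 0.0, "dow": 0.1, "city_month": 0.2},
        climate=ClimateConfig(
            base_mean_c=15.0,
            seasonal_amplitude_c=6.0,
            diurnal_amplitude_c=5.0,
            ar1_sd_c=2.0,
            city_offsets_c=tuple(np.round(np.linspace(-4.0, 4.0, 12), 3)),
        ),
        profile=ProfileConfig(mix_max=0.0),
        holiday_rate=0.15,
    )


@pytest.fixture(scope="session")
def hot_config() -> SyntheticConfig:
    """Small warm-climate config with hot (>30 degC daily) days present."""
    effects = zero_effects()
    effects[">35"] = float(np.log(0.9))
    effects["30-35"] = float(np.log(0.95))
    return SyntheticConfig(
        n_cities=3,
        parks_per_city=2,
        start_date="2017-05-01",
        n_days=60,
        seed=0,
        bin_effects=effects,
        covariate_effects={k: 0.0 for k in DEFAULT_COVARIATES} | {"holiday": 0.2},
        fe_scales={"park": 0.3, "hour": 0.0, "dow": 0.1, "city_month": 0.2},
        climate=ClimateConfig(
            base_mean_c=24.0,
            seasonal_amplitude_c=6.0,
            diurnal_amplitude_c=5.0,
            ar1_sd_c=2.0,
            city_offsets_c=(-3.0, 0.0, 3.0),
        ),
        profile=ProfileConfig(mix_max=0.3, mix_midpoint_c=27.0),
        holiday_rate=0.08,
    )


@pytest.fixture(scope="session")
def hot_panel(hot_config):
    panel, truth = generate_panel(hot_config, seed=5)
    return panel, truth


@pytest.fixture(scope="session")
def study_config():
    from heatrhythm.fixtures import study_2017_config

    return study_2017_config()


@pytest.fixture(scope="session")
def study_panel(study_config):
    """One realisation of the bundled calibrated study panel."""
    panel, truth = generate_panel(study_config, seed=1)
    return panel, truth


def toy_panel() -> pd.DataFrame:
    """Tiny hand-written panel (2 cities, 2 parks, 2 days x 3 hours)."""
    rows = []
    for city, park in [("A", "A1"), ("B", "B1")]:
        for date in ("2017-06-01", "2017-06-02"):
            for hour, temp, visits in [(8, 18.0, 2), (13, 25.0, 3), (20, 22.0, 5)]:
                rows.append((park, city, date, hour, visits, temp))
    df = pd.DataFrame(
        rows, columns=["park_id", "city_id", "date", "hour", "visits", "temperature"]
    )
    df["date"] = pd.to_datetime(df["date"])
    for c in DEFAULT_COVARIATES:
        df[c] = 0.0
    return df
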