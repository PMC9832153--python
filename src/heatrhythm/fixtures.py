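"""Bundled calibrated study configuration (`study_2017`).

Twenty cities spanning cold-temperate to subtropical climates, ten parks
each, 120 days from 1 February 2017 - enough seasonal and latitudinal range
to populate every 5 degC bin from below 0 to above 35 degC.  The
reduced-form bin effects encode the headline dose-response (visitation down
13% above 35 degC, 5% at 30-35 degC, 20% below 0 degC relative to
20-25 degC) and the hot-day redistribution is calibrated so the implied
activity time shift for >30 degC days at the 8 PM reference is 27 minutes.

The structural ``direct_bin_effects`` and the mixture weight ``mix_max``
below were produced by ``scripts/calibrate_study.py`` (deterministic;
rerun it to regenerate them).  ``STUDY_2017_TRUTH`` freezes the calibrated
ground truth the recovery tests compare against.
"""

from __future__ import annotations

import math

import numpy as np

from .calibrate import FIT_BINS  # noqa: F401  (re-exported for callers)
from .synth import ClimateConfig, NoiseConfig, ProfileConfig, SyntheticConfig

#: Reduced-form truths (log scale): the inverted-U dose-response.
STUDY_2017_BIN_EFFECTS = {
    "<0": math.log(0.80),
    "0-5": math.log(0.85),
    "5-10": math.log(0.90),
    "10-15": math.log(0.96),
    "15-20": math.log(0.99),
    "20-25": 0.0,
    "25-30": math.log(0.99),
    "30-35": math.log(0.95),
    ">35": math.log(0.87),
}

#: Calibrated structural hourly effects (from scripts/calibrate_study.py).
STUDY_2017_DIRECT_EFFECTS = {
    '<0': -0.157647,
    '0-5': -0.112004,
    '5-10': -0.06741,
    '10-15': -0.015798,
    '15-20': 0.001465,
    '20-25': 0.0,
    '25-30': 0.003045,
    '30-35': 0.029551,
    '>35': 0.027268
}

#: Calibrated redistribution mixture weight.
STUDY_2017_MIX_MAX = 0.255041

#: Calibrated time shift (minutes) for >30 degC days at the 8 PM reference.
STUDY_2017_DT_TRUE = 27.07

#: Frozen calibrated ground truth per daily-temperature group.
STUDY_2017_TRUTH: dict = {
    'q': {
        '<0': 0.903001,
        '0-5': 0.928446,
        '5-10': 0.960349,
        '10-15': 0.988406,
        '20-25': 1.001707,
        '25-30': 1.008244,
        '>30': 1.019568,
        '15-20': 1.0
    },
    'dt_true': {
        '<0': -9.343,
        '0-5': -7.357,
        '5-10': -4.856,
        '10-15': -2.059,
        '15-20': 0.0,
        '20-25': 4.819,
        '25-30': 17.066,
        '>30': 27.07
    },
    'profiles': {
        '<0': [
            0.014936,
            0.035368,
            0.058732,
            0.076335,
            0.085417,
            0.080129,
            0.068894,
            0.060342,
            0.063584,
            0.072723,
            0.081691,
            0.084375,
            0.074878,
            0.059494,
            0.0444,
            0.026674,
            0.012028
        ],
        '0-5': [
            0.014488,
            0.034481,
            0.057739,
            0.0758,
            0.085456,
            0.080429,
            0.069222,
            0.060674,
            0.063967,
            0.073168,
            0.082162,
            0.084836,
            0.075232,
            0.059687,
            0.044371,
            0.026463,
            0.011823
        ],
        '5-10': [
            0.01436,
            0.034327,
            0.057612,
            0.075678,
            0.085339,
            0.080429,
            0.06927,
            0.060785,
            0.064114,
            0.07334,
            0.082329,
            0.084936,
            0.075286,
            0.059683,
            0.044323,
            0.026406,
            0.011781
        ],
        '10-15': [
            0.014433,
            0.034558,
            0.058071,
            0.076364,
            0.086031,
            0.080755,
            0.069171,
            0.060367,
            0.063475,
            0.072537,
            0.081524,
            0.084394,
            0.075141,
            0.059951,
            0.044692,
            0.026658,
            0.011878
        ],
        '15-20': [
            0.014879,
            0.035547,
            0.05941,
            0.077517,
            0.086222,
            0.080443,
            0.068601,
            0.059689,
            0.062653,
            0.07156,
            0.080471,
            0.083447,
            0.074536,
            0.060247,
            0.045278,
            0.027252,
            0.012247
        ],
        '20-25': [
            0.015359,
            0.036519,
            0.060729,
            0.078867,
            0.08495,
            0.079123,
            0.067473,
            0.058738,
            0.061685,
            0.070467,
            0.079226,
            0.082119,
            0.073318,
            0.062143,
            0.047284,
            0.028854,
            0.013148
        ],
        '25-30': [
            0.01596,
            0.037899,
            0.063004,
            0.081902,
            0.080811,
            0.075516,
            0.064638,
            0.056466,
            0.059422,
            0.067934,
            0.076312,
            0.078921,
            0.070244,
            0.068482,
            0.05346,
            0.033439,
            0.015591
        ],
        '>30': [
            0.016442,
            0.039167,
            0.065344,
            0.085357,
            0.077759,
            0.07267,
            0.062017,
            0.053965,
            0.056641,
            0.064687,
            0.072742,
            0.075437,
            0.067371,
            0.074817,
            0.059701,
            0.037962,
            0.017922
        ]
    }
}


def study_2017_config(seed: int = 0) -> SyntheticConfig:
    """The bundled calibrated synthetic study configuration."""
    return SyntheticConfig(
        n_cities=20,
        parks_per_city=10,
        start_date="2017-02-01",
        n_days=120,
        seed=seed,
        bin_effects=dict(STUDY_2017_BIN_EFFECTS),
        direct_bin_effects=dict(STUDY_2017_DIRECT_EFFECTS),
        covariate_effects={
            "precipitation": -0.010,
            "wind_speed": -0.010,
            "humidity": -0.20,
            "pressure": 0.0,
            "cloud": -0.05,
            "aqi": -0.0005,
            "holiday": 0.30,
        },
        fe_scales={"park": 0.5, "hour": 0.0, "dow": 0.1, "city_month": 0.3},
        climate=ClimateConfig(
            base_mean_c=16.0,
            seasonal_amplitude_c=10.0,
            diurnal_amplitude_c=5.0,
            ar1_sd_c=2.5,
            ar1_rho=0.9,
            city_offsets_c=tuple(np.linspace(-12.0, 11.0, 20).round(3)),
        ),
        profile=ProfileConfig(mix_max=STUDY_2017_MIX_MAX),
        noise=NoiseConfig(family="poisson"),
        holiday_rate=0.08,
        log_daily_visits=math.log(2500.0),
    )


def recover_study_2017(seeds, config: SyntheticConfig | None = None):
    """Run the full estimation pipeline on freshly simulated panels.

    For each seed: simulate a panel from the calibrated configuration, fit
    the hourly binned FE model (terminal bins merged to match the effect
    grid), the daily quantity model and the within-day profiles, and solve
    the >30 degC time shift at the 8 PM reference.  Returns a dict of
    per-seed lists: percentage effects for the three headline bins and the
    recovered shift in minutes.
    """
    from dataclasses import replace

    from . import estimator, synth, timeshift

    cfg = config or study_2017_config()
    spec = estimator.ModelSpec(temperature=FIT_BINS)
    daily_bins = estimator.BinSpec(
        reference=(15.0, 20.0), merge_below=0.0, merge_above=30.0
    )
    out = {"<0": [], "30-35": [], ">35": [], "dt_minutes": [], "n_obs": 0}
    for seed in seeds:
        panel, _ = synth.generate_panel(cfg, seed=seed)
        res = estimator.fit(panel, spec)
        table = res.bin_table()
        for b in ("<0", "30-35", ">35"):
            out[b].append(float(table.loc[b, "pct"]) * 100.0)
        daily_fit = estimator.fit_daily(
            panel, replace(spec, temperature=daily_bins), stat="mean"
        )
        q_curve = timeshift.daily_quantity_curve(daily_fit)
        profile = estimator.fit_hourly_profile(
            panel, spec, temp_groups=["15-20", ">30"]
        )
        shift = timeshift.solve_timeshift(
            profile.rel("15-20"),
            profile.rel(">30"),
            q_curve.q[">30"],
            ref_hour=20.0,
            comparison_group=">30",
        )
        out["dt_minutes"].append(float(shift.dt_minutes))
        out["n_obs"] += len(panel)
    return out
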