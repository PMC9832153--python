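"""Synthetic-panel generator: climate process, truth records, oracle."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatrhythm.errors import InvalidConfigError, UnsolvableShiftError
from heatrhythm.synth import (
    ClimateConfig,
    NoiseConfig,
    ProfileConfig,
    SyntheticConfig,
    dense_timeshift,
    expected_truth,
    generate_climate,
    generate_panel,
    make_climate_deltas,
    make_delayed_profile,
    true_timeshift,
)

from conftest import zero_effects


def flat_climate(mean: float = 20.0) -> ClimateConfig:
    return ClimateConfig(
        base_mean_c=mean,
        seasonal_amplitude_c=0.0,
        diurnal_amplitude_c=0.0,
        ar1_sd_c=0.0,
        city_offsets_c=(0.0,),
    )


class TestClimate:
    def test_degenerate_config_yields_constant_twenty(self):
        cfg = SyntheticConfig(
            n_cities=1, parks_per_city=1, n_days=5,
            bin_effects=zero_effects(), climate=flat_climate(20.0),
        )
        clim = generate_climate(cfg, seed=0)
        assert (clim["temperature"] == 20.0).all()

    def test_diurnal_range_is_twice_the_amplitude(self):
        A = 4.0
        cfg = SyntheticConfig(
            n_cities=1, parks_per_city=1, n_days=3,
            bin_effects=zero_effects(),
            climate=replace(flat_climate(15.0), diurnal_amplitude_c=A),
        )
        clim = generate_climate(cfg, seed=0)
        span = clim.groupby("date")["temperature"].agg(lambda s: s.max() - s.min())
        # the sinusoid peak (3 PM) lies on the hourly grid, so the daily
        # max-min equals 2A exactly
        np.testing.assert_allclose(span.to_numpy(), 2 * A, atol=1e-9)

    def test_seeded_determinism_and_seed_sensitivity(self):
        cfg = SyntheticConfig(
            n_cities=2, parks_per_city=1, n_days=10, bin_effects=zero_effects()
        )
        a = generate_climate(cfg, seed=7)
        b = generate_climate(cfg, seed=7)
        c = generate_climate(cfg, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a["temperature"], c["temperature"])

    def test_invalid_date_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(n_days=0, bin_effects=zero_effects())

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(
                bin_effects=zero_effects(),
                climate=replace(flat_climate(), seasonal_amplitude_c=-1.0),
            )


class TestConfigInvariants:
    def test_reference_bin_must_be_zero(self):
        effects = zero_effects()
        effects["20-25"] = 0.01
        with pytest.raises(InvalidConfigError, match="reference"):
            SyntheticConfig(bin_effects=effects)

    def test_missing_reference_bin_rejected(self):
        effects = zero_effects()
        del effects["20-25"]
        with pytest.raises(InvalidConfigError):
            SyntheticConfig(bin_effects=effects)

    def test_negbin_needs_dispersion(self):
        with pytest.raises(InvalidConfigError):
            NoiseConfig(family="negbin")

    def test_baseline_profile_must_be_nonnegative(self):
        weights = [1.0] * 17
        weights[3] = -0.1
        cfg = ProfileConfig(baseline_weights=tuple(weights))
        with pytest.raises(InvalidConfigError):
            cfg.baseline()

    def test_config_dict_roundtrip(self, study_config):
        again = SyntheticConfig.from_dict(study_config.to_dict())
        assert again.to_dict() == study_config.to_dict()


class TestPanel:
    def test_null_model_poisson_mean(self):
        """All effects zero, flat shares: hourly counts average the daily
        intercept spread uniformly over the 17 hours."""
        c = np.log(1700.0)
        cfg = SyntheticConfig(
            n_cities=2, parks_per_city=2, n_days=40,
            bin_effects=zero_effects(),
            covariate_effects={},
            fe_scales={"park": 0.0, "hour": 0.0, "dow": 0.0, "city_month": 0.0},
            climate=replace(flat_climate(20.0), city_offsets_c=(0.0, 0.0)),
            profile=ProfileConfig(baseline_weights=(1.0,) * 17, mix_max=0.0),
            log_daily_visits=c, holiday_rate=0.0,
        )
        panel, _ = generate_panel(cfg, seed=0)
        lam = np.exp(c) / 17
        tol = 4 * np.sqrt(lam / len(panel))
        assert abs(panel["visits"].mean() - lam) < tol

    def test_hot_bin_ratio_of_means_recovers_effect(self):
        """With FE scales zero and flat shares, the raw mean-visits ratio
        between >35 degC and reference hours equals the configured 0.87."""
        effects = zero_effects()
        effects[">35"] = float(np.log(0.87))
        cfg = SyntheticConfig(
            n_cities=2, parks_per_city=4, n_days=120,
            start_date="2017-05-01",
            bin_effects=effects,
            covariate_effects={},
            fe_scales={"park": 0.0, "hour": 0.0, "dow": 0.0, "city_month": 0.0},
            climate=ClimateConfig(
                base_mean_c=26.0, seasonal_amplitude_c=6.0, diurnal_amplitude_c=6.0,
                ar1_sd_c=2.5, city_offsets_c=(0.0, 0.0),
            ),
            profile=ProfileConfig(baseline_weights=(1.0,) * 17, mix_max=0.0),
            holiday_rate=0.0,
        )
        panel, _ = generate_panel(cfg, seed=1)
        hot = panel.loc[panel["temperature"] >= 35, "visits"].mean()
        ref = panel.loc[
            (panel["temperature"] >= 20) & (panel["temperature"] < 25), "visits"
        ].mean()
        assert hot / ref == pytest.approx(0.87, abs=0.012)

    def test_panel_schema_and_determinism(self, hot_config):
        p1, t1 = generate_panel(hot_config, seed=9)
        p2, _ = generate_panel(hot_config, seed=9)
        pd.testing.assert_frame_equal(p1, p2)
        assert not p1.duplicated(["park_id", "date", "hour"]).any()
        assert p1["hour"].between(6, 22).all()
        assert (p1["visits"] >= 0).all()

    def test_negbin_counts_overdispersed(self, hot_config):
        cfg = replace(hot_config, noise=NoiseConfig(family="negbin", dispersion=0.5))
        p_nb, _ = generate_panel(cfg, seed=3)
        p_po, _ = generate_panel(hot_config, seed=3)
        assert p_nb["visits"].var() > 1.5 * p_po["visits"].var()

    def test_no_redistribution_equalises_evening_share(self):
        """With the redistribution off, the true after-8PM share is the same
        in every daily-temperature group."""
        cfg = SyntheticConfig(
            n_cities=3, parks_per_city=1, n_days=60,
            bin_effects=zero_effects(),
            covariate_effects={},
            fe_scales={"park": 0.0, "hour": 0.0, "dow": 0.0, "city_month": 0.0},
            climate=ClimateConfig(
                base_mean_c=18.0, seasonal_amplitude_c=8.0, diurnal_amplitude_c=4.0,
                ar1_sd_c=2.0, city_offsets_c=(-5.0, 0.0, 5.0),
            ),
            profile=ProfileConfig(mix_max=0.0),
        )
        _, truth = generate_panel(cfg, seed=2)
        shares = {
            g: p[-3:].sum() / p.sum() for g, p in truth.profiles.items()
        }
        vals = np.array(list(shares.values()))
        assert np.ptp(vals) < 1e-12


class TestTruthAndOracle:
    def test_within_day_shares_sum_to_one(self, study_panel):
        _, truth = study_panel
        for g, p in truth.profiles.items():
            assert np.asarray(p).sum() == pytest.approx(1.0, abs=1e-12)
            assert (np.asarray(p) >= 0).all()

    def test_baseline_group_shift_is_exactly_zero(self, study_config):
        assert true_timeshift(study_config, "15-20") == 0.0

    def test_oracle_monotone_in_temperature_group(self, study_config):
        """The redistribution moves strictly more evening mass at higher
        temperatures, so the oracle shift is non-decreasing across groups."""
        truth = expected_truth(study_config, n_reps=2)
        order = [g for g in ["<0", "0-5", "5-10", "10-15", "15-20", "20-25",
                             "25-30", ">30"] if g in truth.dt_true]
        dts = [truth.dt_true[g] for g in order]
        assert all(b >= a - 1e-9 for a, b in zip(dts, dts[1:]))

    def test_pure_translation_gives_sixty_minutes(self):
        """A profile translated one hour later (no mass at the window edges)
        yields exactly a 60-minute shift; whole-hour translations are the
        ones the piecewise-constant convention represents exactly."""
        dens = np.array([0, 1, 2, 3, 4, 4, 3, 2, 2, 3, 4, 4, 3, 2, 1, 0], float)
        base = np.append(dens, 0.0)
        shifted = np.append(np.roll(dens, 1), 0.0)
        dt = dense_timeshift(base / base.sum(), shifted / shifted.sum(), 1.0,
                             ref_hour=19.0)
        assert dt == pytest.approx(60.0, abs=0.06)

    def test_flat_profile_closed_form_sixty_minutes(self):
        """On a uniform profile, q = r(20)/r(21) forces exactly a one-hour
        delay (hand solution of the shift equation)."""
        flat = np.ones(17) / 17
        q = (2 / 16) / (1 / 16)  # r(20) / r(21) = 2
        dt = dense_timeshift(flat, flat, q, ref_hour=20.0)
        assert dt == pytest.approx(60.0, abs=0.06)
        # halving the quantity instead moves the crossing two hours earlier
        dt2 = dense_timeshift(flat, flat, 0.5, ref_hour=20.0)
        assert dt2 == pytest.approx(-120.0, abs=0.06)

    def test_unsolvable_signal(self):
        flat = np.ones(17) / 17
        with pytest.raises(UnsolvableShiftError):
            dense_timeshift(flat, flat, 1e-6, ref_hour=6.5)

    def test_delayed_profile_conserves_mass(self):
        p0 = np.asarray(ProfileConfig().baseline())
        pd_ = make_delayed_profile(p0, evening_delay_h=1.5)
        assert pd_.sum() == pytest.approx(1.0)
        assert (pd_ >= 0).all()
        # mass moved out of midday, into morning and evening
        assert pd_[4:13].sum() < p0[4:13].sum()
        assert pd_[13:].sum() > p0[13:].sum()

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        mix=st.floats(0.0, 0.9),
        tbar=st.floats(-5.0, 40.0),
    )
    def test_mixture_shares_always_sum_to_one(self, mix, tbar):
        prof = ProfileConfig(mix_max=mix)
        shares = prof.day_shares(np.array([tbar]))
        assert shares.sum() == pytest.approx(1.0, abs=1e-12)
        assert (shares >= 0).all()


class TestDeltas:
    def test_fabricated_deltas_complete_and_deterministic(self):
        d1 = make_climate_deltas(n_models=5, cells=("A", "B"), seed=3)
        d2 = make_climate_deltas(n_models=5, cells=("A", "B"), seed=3)
        pd.testing.assert_frame_equal(d1, d2)
        assert (d1.groupby(["model", "cell"])["month"].nunique() == 12).all()
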