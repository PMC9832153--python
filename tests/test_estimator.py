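"""Fixed-effects estimator: design construction, absorption, inference."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from heatrhythm import estimator
from heatrhythm.errors import BinningError, CollinearityError, PanelValidationError
from heatrhythm.estimator import (
    BinSpec,
    ModelSpec,
    absorb_fixed_effects,
    aggregate_daily,
    build_design,
    fit,
    fit_hourly_profile,
    fit_periods,
    fit_stratified,
)
from heatrhythm.synth import SyntheticConfig, generate_panel

from conftest import toy_panel, zero_effects


# ---------------------------------------------------------------------------
# Bins and design
# ---------------------------------------------------------------------------


class TestBinsAndDesign:
    def test_log1p_outcome_and_reference_indicators(self):
        panel = toy_panel()
        panel.loc[panel.index[0], "visits"] = 0
        panel.loc[panel.index[1], "temperature"] = 22.0
        d = build_design(panel, ModelSpec())
        assert d.y[0] == 0.0  # log(0 + 1)
        # a 22 degC observation sits in the reference bin: all indicators 0
        assert d.X.loc[panel.index[1], d.bin_columns].sum() == 0.0

    def test_merged_terminal_bin_indicator(self):
        panel = toy_panel()
        panel.loc[panel.index[0], "temperature"] = 31.0
        spec = ModelSpec(temperature=BinSpec(merge_below=0.0, merge_above=30.0))
        d = build_design(panel, spec)
        assert d.X.loc[panel.index[0], ">30"] == 1.0

    def test_explicit_edges_enforce_coverage(self):
        panel = toy_panel()
        panel.loc[panel.index[0], "temperature"] = 31.0
        spec = ModelSpec(temperature=BinSpec(edges=(0.0, 10.0, 20.0, 30.0)))
        with pytest.raises(BinningError):
            build_design(panel, spec)

    def test_empty_nonreference_bin_dropped(self, caplog):
        panel = toy_panel()
        panel["temperature"] = np.resize([2.0, 22.0], len(panel))
        d = build_design(panel, ModelSpec())
        assert "10-15" in d.dropped_bins or "5-10" in d.dropped_bins
        assert all(lab not in d.X.columns for lab in d.dropped_bins)

    def test_three_degree_bins_have_narrow_reference(self):
        spec = BinSpec(width=3.0)
        rb = spec.resolve(np.linspace(0, 35, 100))
        lo_lab = rb.reference_label
        # the reference is the 3-degree bin containing 22.5 degC
        assert rb.midpoints[rb.reference_index] == pytest.approx(22.5, abs=1.5)
        assert "-" in lo_lab

    def test_hour_validation(self):
        panel = toy_panel()
        panel.loc[panel.index[0], "hour"] = 23
        with pytest.raises(PanelValidationError, match="hour"):
            build_design(panel, ModelSpec())


# ---------------------------------------------------------------------------
# Fixed-effect absorption
# ---------------------------------------------------------------------------


class TestAbsorption:
    def test_single_dimension_equals_group_mean_subtraction(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=60)
        X = rng.normal(size=(60, 2))
        codes = rng.integers(0, 5, 60)
        yd, Xd, sweeps = absorb_fixed_effects(y, X, [codes])
        df = pd.DataFrame({"y": y, "g": codes})
        expected = y - df.groupby("g")["y"].transform("mean").to_numpy()
        np.testing.assert_allclose(yd, expected, atol=1e-12)

    def test_constant_column_demeaned_to_zero(self):
        y = np.ones(30)
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        codes = [np.repeat(np.arange(3), 10), np.tile(np.arange(10), 3)]
        yd, Xd, _ = absorb_fixed_effects(y, X, codes)
        assert np.abs(yd).max() < 1e-10
        assert np.abs(Xd[:, 0]).max() < 1e-10

    def test_absorbed_ols_matches_explicit_dummy_ols(self):
        """Within-estimator coefficients equal full dummy-variable OLS."""
        cfg = SyntheticConfig(
            n_cities=2,
            parks_per_city=1,
            n_days=10,
            seed=3,
            bin_effects=zero_effects(),
            fe_scales={"park": 0.3, "hour": 0.2, "dow": 0.1, "city_month": 0.2},
        )
        panel, _ = generate_panel(cfg, seed=3)
        assert len(panel) <= 500
        spec = ModelSpec(covariates=("precipitation", "wind_speed", "humidity"))
        res = fit(panel, spec)
        d = build_design(panel, spec)
        dummies = [
            pd.get_dummies(codes, prefix=name, drop_first=True).astype(float)
            for codes, name in zip(d.fe_codes, d.fe_names)
        ]
        Z = pd.concat([d.X.reset_index(drop=True)] + [dm.reset_index(drop=True) for dm in dummies], axis=1)
        Z.insert(0, "_const", 1.0)
        beta, *_ = np.linalg.lstsq(Z.to_numpy(), d.y, rcond=None)
        explicit = pd.Series(beta, index=Z.columns)[d.X.columns]
        np.testing.assert_allclose(
            res.params.to_numpy(), explicit.to_numpy(), atol=1e-6, rtol=1e-6
        )

    def test_fe_spanned_column_is_annihilated_and_flagged(self):
        """A regressor lying in the FE span demeans to zero and is reported
        as collinear rather than silently shifting the bin coefficients."""
        panel = toy_panel()
        spec = ModelSpec(covariates=("precipitation",))
        d = build_design(panel, spec)
        spanned = pd.get_dummies(panel["hour"]).iloc[:, 0].to_numpy(float)
        X = np.column_stack([d.X.to_numpy(), spanned])
        yd, Xd, _ = absorb_fixed_effects(d.y, X, d.fe_codes)
        assert np.abs(Xd[:, -1]).max() < 1e-8
        panel2 = panel.assign(precipitation=spanned)
        with pytest.raises(CollinearityError, match="precipitation"):
            fit(panel2, spec)


# ---------------------------------------------------------------------------
# Cluster-robust inference
# ---------------------------------------------------------------------------


class TestClusteredInference:
    def test_sandwich_matches_hand_computation(self):
        """CR1 covariance equals an explicitly looped sandwich on 6 rows."""
        X = np.array([[1.0, 0.2], [0.5, -1.0], [0.3, 0.7],
                      [-0.4, 0.1], [1.2, 0.4], [0.0, -0.6]])
        u = np.array([0.5, -0.2, 0.1, 0.3, -0.4, 0.2])
        clusters = np.array([0, 0, 0, 1, 1, 1])
        cov, dof = estimator._cluster_covariance(X, u, clusters, 2, k_model=2)
        bread = np.linalg.inv(X.T @ X)
        meat = np.zeros((2, 2))
        for g in (0, 1):
            s = X[clusters == g].T @ u[clusters == g]
            meat += np.outer(s, s)
        factor = (2 / 1) * (5 / 4)
        np.testing.assert_allclose(cov, factor * bread @ meat @ bread, rtol=1e-12)
        assert dof == 4

    def test_against_statsmodels_single_fe(self):
        """With one absorbed dimension, coefficients and clustered SEs match
        a statsmodels OLS with explicit dummies exactly."""
        sm = pytest.importorskip("statsmodels.api")
        cfg = SyntheticConfig(
            n_cities=3, parks_per_city=2, n_days=8, seed=2,
            bin_effects=zero_effects(),
            fe_scales={"park": 0.4, "hour": 0.0, "dow": 0.0, "city_month": 0.0},
        )
        panel, _ = generate_panel(cfg, seed=2)
        spec = ModelSpec(fe_dims=("park",), covariates=("precipitation", "wind_speed"))
        res = fit(panel, spec)
        d = build_design(panel, spec)
        Z = pd.concat(
            [d.X.reset_index(drop=True),
             pd.get_dummies(d.fe_codes[0], prefix="park").astype(float)],
            axis=1,
        )
        ols = sm.OLS(d.y, Z.to_numpy()).fit(
            cov_type="cluster", cov_kwds={"groups": d.cluster_codes}
        )
        k = d.X.shape[1]
        np.testing.assert_allclose(res.params.to_numpy(), ols.params[:k], rtol=1e-8)
        np.testing.assert_allclose(res.se.to_numpy(), ols.bse[:k], rtol=1e-6)

    def test_clustered_at_least_hc_under_cluster_shocks(self, null_config):
        """With injected city-date shocks, clustered SEs exceed plain
        heteroskedasticity-robust SEs on average."""
        ratios = []
        for seed in (0, 1, 2):
            panel, _ = generate_panel(null_config, seed=seed)
            rng = np.random.default_rng(seed)
            key = panel["city_id"].astype(str) + panel["date"].astype(str)
            codes, uniq = pd.factorize(key)
            shock = rng.normal(0.0, 0.3, len(uniq))
            panel = panel.assign(
                visits=rng.poisson(
                    np.maximum(panel["visits"].to_numpy(), 1) * np.exp(shock[codes])
                )
            )
            spec = ModelSpec()
            res = fit(panel, spec)
            d = build_design(panel, spec)
            yd, Xd, _ = absorb_fixed_effects(d.y, d.X.to_numpy(), d.fe_codes)
            beta, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
            u = yd - Xd @ beta
            bread = np.linalg.inv(Xd.T @ Xd)
            hc = bread @ (Xd * (u**2)[:, None]).T @ Xd @ bread
            hc_se = np.sqrt(np.diag(hc))
            ratios.append(float((res.se.to_numpy() / hc_se).mean()))
        assert np.mean(ratios) > 1.0

    def test_covariance_symmetric_psd(self, hot_panel):
        panel, _ = hot_panel
        res = fit(panel, ModelSpec())
        C = res.cov.to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.linalg.eigvalsh(C).min() > -1e-12

    def test_pct_effects_are_endpoint_transforms(self, hot_panel):
        panel, _ = hot_panel
        tidy = fit(panel, ModelSpec()).tidy()
        np.testing.assert_allclose(tidy["pct"], np.expm1(tidy["beta"]))
        np.testing.assert_allclose(tidy["pct_low"], np.expm1(tidy["ci_low"]))


# ---------------------------------------------------------------------------
# Daily aggregation and variants
# ---------------------------------------------------------------------------


class TestDailyAndVariants:
    def test_aggregate_daily_hand_arithmetic(self):
        panel = toy_panel()
        one = panel[panel.park_id == "A1"].iloc[:3].copy()
        one["temperature"] = [18.0, 25.0, 31.0]
        one["visits"] = [2, 3, 5]
        for stat, expected in [("min", 18.0), ("mean", 74 / 3), ("max", 31.0)]:
            daily = aggregate_daily(one, stat)
            assert daily["temperature"].iloc[0] == pytest.approx(expected)
            assert daily["visits"].iloc[0] == 10

    def test_constant_day_min_mean_max_agree(self):
        panel = toy_panel()
        panel["temperature"] = 20.0
        vals = [aggregate_daily(panel, s)["temperature"].iloc[0] for s in
                ("min", "mean", "max")]
        assert vals == [20.0, 20.0, 20.0]

    def test_hour_13_belongs_to_noon(self):
        assert 13 in estimator.PERIODS["noon"]
        assert 14 in estimator.PERIODS["noon"]  # the 2-3 PM hour is hot-side

    def test_periods_reveal_substitution_signs(self, study_panel):
        """On the calibrated panel, hot days depress noon/afternoon activity
        and raise morning/evening activity relative to comfortable days."""
        panel, _ = study_panel
        spec = ModelSpec(
            temperature=BinSpec(merge_below=0.0, merge_above=30.0)
        )
        fits = fit_periods(panel, spec)
        hot = {name: f.bin_table().loc[">30", "beta"] for name, f in fits.items()}
        assert hot["noon"] < 0 and hot["late_afternoon"] < 0
        assert hot["morning"] > 0 and hot["evening"] > 0

    def test_quadratic_and_binned_peaks_agree(self, study_panel):
        panel, _ = study_panel
        from heatrhythm.calibrate import FIT_BINS

        binned = fit(panel, ModelSpec(temperature=FIT_BINS))
        bt = binned.bin_table()
        binned_peak = bt["midpoint"][bt["beta"].idxmax()]
        poly = fit(panel, ModelSpec(temperature="poly2"))
        b1, b2 = poly.params["temp_c"], poly.params["temp_c_sq"]
        assert b2 < 0  # inverted U
        center = panel["temperature"].mean()
        poly_peak = center - b1 / (2 * b2)
        assert abs(poly_peak - binned_peak) <= 5.0

    def test_hourly_profile_reference_is_zero(self, study_panel):
        panel, _ = study_panel
        prof = fit_hourly_profile(panel, ModelSpec(), temp_groups=["15-20"])
        i13 = list(prof.hours).index(13)
        assert prof.beta["15-20"][i13] == 0.0
        assert prof.se["15-20"][i13] == 0.0

    def test_flat_shares_give_flat_profile(self):
        from heatrhythm.synth import ClimateConfig, ProfileConfig

        cfg = SyntheticConfig(
            n_cities=3, parks_per_city=2, n_days=30, seed=4,
            bin_effects=zero_effects(),
            covariate_effects={},
            fe_scales={"park": 0.2, "hour": 0.0, "dow": 0.0, "city_month": 0.1},
            climate=ClimateConfig(
                base_mean_c=17.5, seasonal_amplitude_c=0.0,
                diurnal_amplitude_c=2.0, ar1_sd_c=1.0,
                city_offsets_c=(0.0, 0.0, 0.0),
            ),
            profile=ProfileConfig(baseline_weights=(1.0,) * 17, mix_max=0.0),
        )
        panel, _ = generate_panel(cfg, seed=4)
        prof = fit_hourly_profile(panel, ModelSpec(covariates=()))
        assert prof.groups  # narrow climate: whatever groups exist are flat
        for g in prof.groups:
            assert np.abs(prof.beta[g]).max() < 0.03

    def test_profile_errors_on_missing_hours(self, study_panel):
        panel, _ = study_panel
        crippled = panel[panel["hour"] != 9]
        with pytest.raises(PanelValidationError, match="9"):
            fit_hourly_profile(crippled, ModelSpec(), temp_groups=["15-20"])


# ---------------------------------------------------------------------------
# Stratified fits and null recovery
# ---------------------------------------------------------------------------


class TestStratifiedAndNull:
    def test_stratified_recovers_differential_effects(self):
        from heatrhythm.synth import ClimateConfig

        effects = zero_effects()
        effects[">35"] = float(np.log(0.9))
        effects["30-35"] = float(np.log(0.95))
        cfg = SyntheticConfig(
            n_cities=6, parks_per_city=4, n_days=60, seed=6,
            bin_effects=effects,
            covariate_effects={},
            fe_scales={"park": 0.2, "hour": 0.0, "dow": 0.0, "city_month": 0.1},
            climate=ClimateConfig(
                base_mean_c=26.0, seasonal_amplitude_c=5.0, diurnal_amplitude_c=5.0,
                ar1_sd_c=2.0, city_offsets_c=(-2.0, -1.0, 0.0, 1.0, 2.0, 4.0),
            ),
            start_date="2017-06-01",
            strata_effects={"urban": {1: {">35": -0.4, "30-35": -0.4}}},
        )
        panel, _ = generate_panel(cfg, seed=6)
        fits = fit_stratified(panel, ModelSpec(covariates=()), "urban")
        assert set(fits) == {0, 1}
        b0 = fits[0].bin_table().loc[">30", "beta"]
        b1 = fits[1].bin_table().loc[">30", "beta"]
        assert b1 < b0  # urban parks configured more heat-sensitive

    def test_singleton_cluster_stratum_skipped(self, hot_panel, caplog):
        panel, _ = hot_panel
        panel = panel.copy()
        panel["urban"] = (panel["city_id"] == "C01").astype(int)
        with caplog.at_level("WARNING"):
            fits = fit_stratified(panel, ModelSpec(), "urban")
        assert list(fits) == [0]
        assert any("skipped" in r.message for r in caplog.records)

    def test_null_dgp_cis_cover_zero(self, null_config):
        """Zero-effect generator: 95% CIs on interior bin effects cover 0 at
        close to the nominal rate across seeds.  Terminal bins are excluded:
        their observations concentrate in one or two cities, where
        cluster-robust intervals are known to undercover."""
        covered = total = 0
        for seed in range(10):
            panel, _ = generate_panel(null_config, seed=100 + seed)
            tidy = fit(panel, ModelSpec()).tidy()
            bins = [i for i in tidy.index if i[0].isdigit()]
            sub = tidy.loc[bins]
            covered += int(((sub["ci_low"] <= 0) & (sub["ci_high"] >= 0)).sum())
            total += len(sub)
        assert total >= 30
        assert covered / total >= 0.85
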