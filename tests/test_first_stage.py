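"""Quasi-Poisson fitting, seasons, episodes, and the lead-exposure check."""

import math

import numpy as np
import pandas as pd
import pytest

import tvmort as tm
from tvmort.first_stage import build_design, fit_quasipoisson


class TestQuasiPoisson:
    def test_intercept_only_is_log_mean_exactly(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(40.0, 500).astype(float)
        fit = fit_quasipoisson(np.ones((500, 1)), y)
        assert fit.coefficients[0] == pytest.approx(math.log(y.mean()), abs=1e-10)

    def test_dispersion_near_one_under_poisson_sampling(self):
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.normal(size=n)
        mu = np.exp(3.0 + 0.1 * x)
        y = rng.poisson(mu).astype(float)
        fit = fit_quasipoisson(np.column_stack([np.ones(n), x]), y)
        # Pearson X2/(n-p) has mean 1, variance ~ 2/n under the Poisson model
        assert abs(fit.dispersion - 1.0) < 3 * math.sqrt(2.0 / n)

    def test_point_estimates_unchanged_ses_scale_with_dispersion(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=n)
        mu = np.exp(2.0 + 0.2 * x)
        # overdispersed counts: gamma-mixed Poisson
        y = rng.poisson(rng.gamma(mu / 1.5, 1.5)).astype(float)
        X = np.column_stack([np.ones(n), x])
        import statsmodels.api as sm
        plain = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        quasi = fit_quasipoisson(X, y)
        assert np.allclose(quasi.coefficients, plain.params, atol=1e-8)
        assert np.allclose(quasi.se(), plain.bse * math.sqrt(quasi.dispersion),
                           rtol=1e-6)

    def test_rank_deficiency_reported(self):
        X = np.column_stack([np.ones(100), np.ones(100)])
        with pytest.raises(ValueError, match="rank"):
            fit_quasipoisson(X, np.full(100, 5.0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_quasipoisson(np.ones((10, 1)), np.array([1.0] * 9 + [-1.0]))


class TestFitCommunity:
    def test_recovers_known_tv_effect(self, sim_community):
        series, mp = sim_community
        r = tm.fit_community(series, tm.ModelConfig(), community_id="sim")
        assert abs(r.tv_coefficient - mp.tv_effect) < 3 * r.tv_se
        assert r.ci_low < r.percent_change_per_iqr < r.ci_high
        assert r.dispersion > 1.0  # generator is overdispersed (phi = 1.3)
        assert r.percent_change_per_iqr == pytest.approx(
            100 * (math.exp(r.tv_coefficient * r.iqr) - 1))

    def test_temperature_shift_leaves_tv_coefficient_unchanged(self, sim_community):
        series, _ = sim_community
        r1 = tm.fit_community(series, tm.ModelConfig(), community_id="a")
        shifted = series.copy()
        shifted[["tmin", "tmean", "tmax"]] += 10.0
        r2 = tm.fit_community(shifted, tm.ModelConfig(), community_id="b")
        # TV is shift-invariant and the temperature basis reparameterizes
        assert r2.tv_coefficient == pytest.approx(r1.tv_coefficient, rel=1e-6)
        assert r2.tv_se == pytest.approx(r1.tv_se, rel=1e-6)

    def test_dropped_days_accounted_for(self, sim_community):
        series, _ = sim_community
        cfg = tm.ModelConfig(max_lag=21)
        r = tm.fit_community(series, cfg, community_id="sim")
        assert r.n_days_used + r.n_days_dropped == len(series)
        assert r.n_days_dropped >= cfg.max_lag  # lag burn-in at least

    def test_humidity_config_requires_column(self, sim_community):
        series, _ = sim_community
        with pytest.raises(ValueError, match="rh"):
            tm.fit_community(series, tm.ModelConfig(include_humidity=True))

    def test_short_series_rejected(self):
        wp = tm.WeatherParams()
        s = tm.simulate_community(wp, tm.MortalityParams(), 200, seed=0)
        with pytest.raises(ValueError):
            tm.fit_community(s, tm.ModelConfig())

    def test_sensitivity_configs_fit(self, sim_community):
        # 28-day lag, 3 and 6 temperature df, heat-wave/cold-spell terms,
        # min+max control: all must produce a finite, compatible estimate
        series, _ = sim_community
        base = tm.fit_community(series, tm.ModelConfig(), community_id="s")
        for cfg in [
            tm.ModelConfig(max_lag=28),
            tm.ModelConfig(temp_df=3),
            tm.ModelConfig(temp_df=6),
            tm.ModelConfig(include_heatwave_coldspell=True),
            tm.ModelConfig(control_variable="min_and_max_temperature"),
            tm.ModelConfig(control_variable="none"),
        ]:
            r = tm.fit_community(series, cfg, community_id="s")
            assert np.isfinite(r.tv_coefficient) and np.isfinite(r.tv_se)
        # well-specified generator: 21 vs 28 lag days barely moves the estimate
        r28 = tm.fit_community(series, tm.ModelConfig(max_lag=28), community_id="s")
        assert abs(r28.tv_coefficient - base.tv_coefficient) < base.tv_se

    def test_dow_reference_category_immaterial_for_tv(self, sim_community):
        # dropping a different weekday dummy reparameterizes the same space
        series, _ = sim_community
        cfg = tm.ModelConfig()
        X, y, used, tv, slices = build_design(series, cfg)
        fit1 = fit_quasipoisson(X, y)
        dow = pd.DatetimeIndex(series["date"]).dayofweek.to_numpy()[used]
        alt = np.column_stack([(dow == d).astype(float) for d in (0, 1, 2, 3, 4, 5)])
        X2 = X.copy()
        X2[:, slices["dow"]] = alt  # Sunday reference instead of Monday
        fit2 = fit_quasipoisson(X2, y)
        j = slices["tv"].start
        assert fit2.coefficients[j] == pytest.approx(fit1.coefficients[j], rel=1e-6)


class TestSeasons:
    def make_sinusoidal(self, phase, n=1461, seed=0):
        wp = tm.WeatherParams(seasonal_phase=phase, daily_noise_sd=0.5)
        return tm.simulate_weather(wp, n, seed=seed)

    def test_northern_hemisphere_hot_block_around_july(self):
        # peak near early July -> hot block contiguous around it
        s = self.make_sinusoidal(-math.pi / 2)
        labels = tm.assign_seasons(s)
        hot = {m for m, v in labels.month_to_season.items() if v == "hot"}
        assert hot in ({5, 6, 7, 8}, {6, 7, 8, 9})
        cold = {m for m, v in labels.month_to_season.items() if v == "cold"}
        assert cold & {12, 1, 2}

    def test_southern_hemisphere_blocks_swap(self):
        north = tm.assign_seasons(self.make_sinusoidal(-math.pi / 2))
        south = tm.assign_seasons(self.make_sinusoidal(math.pi / 2))
        n_hot = {m for m, v in north.month_to_season.items() if v == "hot"}
        s_cold = {m for m, v in south.month_to_season.items() if v == "cold"}
        assert len(n_hot & s_cold) >= 3  # antiphase up to month-boundary effects

    def test_constant_series_tie_break_deterministic(self):
        df = pd.DataFrame({"date": pd.date_range("2000-01-01", periods=730),
                           "tmean": 10.0, "tmin": 8.0, "tmax": 12.0})
        labels = tm.assign_seasons(df)
        assert labels.tie_broken
        assert [labels.month_to_season[m] for m in range(1, 13)] == (
            ["cold"] * 4 + ["moderate"] * 4 + ["hot"] * 4)

    def test_missing_month_rejected(self):
        df = pd.DataFrame({"date": pd.date_range("2000-01-01", periods=200),
                           "tmean": 10.0, "tmin": 8.0, "tmax": 12.0})
        with pytest.raises(ValueError, match="month"):
            tm.assign_seasons(df)

    def test_each_season_gets_four_months(self, sim_community):
        series, _ = sim_community
        labels = tm.assign_seasons(series)
        counts = pd.Series(labels.month_to_season).value_counts()
        assert counts.to_dict() == {"cold": 4, "hot": 4, "moderate": 4}


class TestSeasonal:
    def test_season_day_counts_partition_fitted_days(self, sim_community):
        series, _ = sim_community
        labels = tm.assign_seasons(series)
        season = labels.of_dates(series["date"])
        cfg = tm.ModelConfig()
        X, y, used, tv, slices = build_design(series, cfg)
        counts = pd.Series(season[used]).value_counts()
        assert counts.sum() == used.sum()

    def test_homogeneous_effect_yields_compatible_slopes(self, sim_community):
        series, mp = sim_community
        out = tm.fit_seasonal(series, tm.ModelConfig())
        assert set(out) == {"cold", "moderate", "hot"}
        for s1 in out:
            for s2 in out:
                diff = abs(out[s1].coefficient - out[s2].coefficient)
                se = math.hypot(out[s1].se, out[s2].se)
                assert diff < 3 * se  # same true slope in every season
            assert abs(out[s1].coefficient - mp.tv_effect) < 3.5 * out[s1].se


class TestEpisodes:
    def make(self, tmean):
        n = len(tmean)
        return pd.DataFrame({"date": pd.date_range("2000-01-01", periods=n),
                             "tmean": tmean,
                             "tmin": np.asarray(tmean) - 2,
                             "tmax": np.asarray(tmean) + 2})

    def base_series(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(15.0, 1.0, n)

    def test_two_day_exceedance_not_flagged(self):
        t = self.base_series()
        t[100:102] = 40.0  # two consecutive days above the 95th percentile
        heat, _ = tm.detect_episodes(self.make(t))
        assert not heat.any()

    def test_three_day_run_flags_all_three(self):
        t = self.base_series()
        t[100:103] = 40.0
        heat, cold = tm.detect_episodes(self.make(t))
        assert heat[100:103].all() and heat.sum() == 3
        t2 = self.base_series()
        t2[200:204] = -10.0
        heat2, cold2 = tm.detect_episodes(self.make(t2))
        assert cold2[200:204].all() and cold2.sum() == 4

    def test_constant_series_has_no_episodes(self):
        heat, cold = tm.detect_episodes(self.make(np.full(300, 10.0)))
        assert not heat.any() and not cold.any()

    def test_run_at_series_end_counted(self):
        t = self.base_series()
        t[-3:] = 40.0
        heat, _ = tm.detect_episodes(self.make(t))
        assert heat[-3:].all()


class TestGrangerCheck:
    def test_zero_leads_rejected(self, sim_community):
        series, _ = sim_community
        with pytest.raises(ValueError):
            tm.granger_lead_check(series, tm.ModelConfig(), leads=0)

    def test_returns_one_row_per_lead_with_finite_estimates(self, sim_community):
        series, _ = sim_community
        out = tm.granger_lead_check(series, tm.ModelConfig(), leads=3)
        assert list(out["lead"]) == [1, 2, 3]
        assert np.isfinite(out[["coefficient", "se", "z"]].to_numpy()).all()
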