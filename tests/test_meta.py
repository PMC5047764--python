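"""ML random-effects pooling: oracles, recovery, zone assignment."""

import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import tvmort as tm
from tvmort.meta import _neg_loglik


def grid_search_tau2(y, se, hi=10.0, step=1e-4):
    """Brute-force profile-likelihood oracle over tau^2."""
    y = np.asarray(y, float)
    v = np.asarray(se, float) ** 2
    taus = np.arange(0.0, hi, step)
    nll = [_neg_loglik(t, y, v, reml=False) for t in taus]
    return taus[int(np.argmin(nll))]


class TestPoolRandomEffects:
    def test_identical_estimates_pool_to_common_value(self):
        p = tm.pool_random_effects([0.3] * 5, [0.1] * 5)
        assert p.mu == pytest.approx(0.3)
        assert p.tau2 == pytest.approx(0.0, abs=1e-10)
        assert p.I2 == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_two_study_case_matches_grid_oracle(self):
        y, se = [0.0, 1.0], [1.0, 1.0]
        p = tm.pool_random_effects(y, se)
        assert p.mu == pytest.approx(0.5)
        assert p.tau2 == pytest.approx(grid_search_tau2(y, se), abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_instances_match_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 4)
        y = rng.normal(0.5, 0.8, k)
        se = rng.uniform(0.2, 1.0, k)
        p = tm.pool_random_effects(y, se)
        oracle = grid_search_tau2(y, se)
        assert p.tau2 == pytest.approx(oracle, abs=2e-4)
        # and the profile mean at the oracle tau2 matches mu
        w = 1.0 / (se**2 + oracle)
        assert p.mu == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-3)

    def test_recovery_of_mu_and_tau(self):
        rng = np.random.default_rng(3)
        mu, tau, k, reps = 0.5, 0.2, 100, 200
        mus, taus = [], []
        for _ in range(reps):
            se = rng.uniform(0.05, 0.3, k)
            y = rng.normal(mu, np.sqrt(tau**2 + se**2))
            p = tm.pool_random_effects(y, se)
            mus.append(p.mu)
            taus.append(math.sqrt(p.tau2))
        se_mu = np.std(mus, ddof=1) / math.sqrt(reps)
        se_tau = np.std(taus, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(mus) - mu) < 3 * se_mu
        # ML tau has small-k downward bias; at k=100 it is within MC noise
        assert abs(np.mean(taus) - tau) < 3 * se_tau + 0.01

    def test_tau2_boundary_when_heterogeneity_below_noise(self):
        # spread of estimates well inside the within-study noise
        y = np.array([0.10, 0.11, 0.09, 0.105])
        se = np.array([0.5, 0.5, 0.5, 0.5])
        p = tm.pool_random_effects(y, se)
        assert p.tau2 == 0.0

    def test_pooled_estimate_within_convex_hull(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.normal(0, 1, 6)
            se = rng.uniform(0.1, 1.0, 6)
            p = tm.pool_random_effects(y, se)
            assert y.min() - 1e-12 <= p.mu <= y.max() + 1e-12

    def test_single_community_passthrough(self):
        p = tm.pool_random_effects([0.2], [0.05])
        assert p.mu == 0.2 and p.se == 0.05
        assert math.isnan(p.tau2)

    def test_coverage_of_pooled_ci(self):
        rng = np.random.default_rng(12)
        mu, tau, k, reps = 0.3, 0.15, 100, 200
        hits = 0
        for _ in range(reps):
            se = rng.uniform(0.05, 0.3, k)
            y = rng.normal(mu, np.sqrt(tau**2 + se**2))
            p = tm.pool_random_effects(y, se)
            lo = p.mu - 1.959963984540054 * p.se
            hi = p.mu + 1.959963984540054 * p.se
            hits += lo <= mu <= hi
        assert 0.92 <= hits / reps <= 0.98

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_metafor_ml_estimates(self, tmp_path):
        # independent reference implementation on a small fixture
        rng = np.random.default_rng(21)
        y = rng.normal(0.4, 0.5, 8)
        se = rng.uniform(0.1, 0.5, 8)
        script = tmp_path / "rma.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"y <- c({', '.join(f'{float(v):.15g}' for v in y)})\n"
            f"se <- c({', '.join(f'{float(v):.15g}' for v in se)})\n"
            "f <- rma(yi=y, sei=se, method='ML')\n"
            "cat(sprintf('%.10f %.10f %.10f', f$beta[1], f$se, f$tau2))\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        r_mu, r_se, r_tau2 = map(float, out.stdout.split())
        p = tm.pool_random_effects(y, se)
        assert p.mu == pytest.approx(r_mu, abs=1e-6)
        assert p.tau2 == pytest.approx(r_tau2, abs=1e-6)
        assert p.se == pytest.approx(r_se, abs=1e-6)


class TestClimateZones:
    def test_eight_distinct_communities_split_two_per_zone(self):
        meta = pd.DataFrame({"community_id": [f"c{i}" for i in range(8)],
                             "annual_mean_temp": np.arange(8.0)})
        zones = tm.assign_climate_zones(meta)
        assert zones.value_counts().to_dict() == {
            "cold": 2, "moderate_cold": 2, "moderate_hot": 2, "hot": 2}

    def test_degenerate_equal_temps_all_cold(self):
        meta = pd.DataFrame({"community_id": ["a", "b", "c"],
                             "annual_mean_temp": [10.0, 10.0, 10.0]})
        zones = tm.assign_climate_zones(meta)
        assert (zones == "cold").all()

    def test_assignment_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        meta = pd.DataFrame({"community_id": [f"c{i}" for i in range(12)],
                             "annual_mean_temp": rng.uniform(0, 30, 12)})
        shuffled = meta.sample(frac=1, random_state=1)
        z1 = tm.assign_climate_zones(meta).sort_index()
        z2 = tm.assign_climate_zones(shuffled).sort_index()
        pd.testing.assert_series_equal(z1, z2)

    def test_boundary_bracket_convention(self):
        # value exactly at the 25th percentile goes to 'cold' (<= convention)
        meta = pd.DataFrame({"community_id": list("abcde"),
                             "annual_mean_temp": [0.0, 1.0, 2.0, 3.0, 4.0]})
        zones = tm.assign_climate_zones(meta)
        assert zones["b"] == "cold"  # 1.0 == q25
        assert zones["e"] == "hot"   # 4.0 > q75


class TestPoolByGroup:
    def make_results(self, k=6):
        rng = np.random.default_rng(0)
        return pd.DataFrame({
            "community_id": [f"c{i}" for i in range(k)],
            "tv_window": 1,
            "season": "all",
            "coefficient": rng.normal(0.01, 0.005, k),
            "se": rng.uniform(0.002, 0.01, k),
        })

    def test_single_group_equals_direct_pooling(self):
        df = self.make_results()
        groups = pd.Series("all", index=df["community_id"].values)
        table = tm.pool_by_group(df, groups)
        direct = tm.pool_random_effects(df["coefficient"].to_numpy(),
                                        df["se"].to_numpy())
        assert len(table) == 1
        row = table.iloc[0]
        assert row["pooled_log_effect"] == pytest.approx(direct.mu)
        assert row["tau2"] == pytest.approx(direct.tau2, abs=1e-10)
        assert row["percent_change"] == pytest.approx(direct.percent_change)

    def test_one_row_per_group_window_season(self):
        df = pd.concat([self.make_results().assign(tv_window=w) for w in (1, 2, 3)],
                       ignore_index=True)
        groups = pd.Series(["g1", "g1", "g1", "g2", "g2", "g2"] ,
                           index=self.make_results()["community_id"].values)
        table = tm.pool_by_group(df, groups)
        assert len(table) == 6  # 2 groups x 3 windows
        assert set(zip(table["group"], table["tv_window"])) == {
            (g, w) for g in ("g1", "g2") for w in (1, 2, 3)}

    def test_unlabelled_communities_skipped(self):
        df = self.make_results()
        groups = pd.Series({"c0": "g", "c1": "g", "c2": "g"})
        table = tm.pool_by_group(df, groups)
        assert table.iloc[0]["n_communities"] == 3
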