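import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermokinesis import exploration_stats as es
from thermokinesis import nav_simulator as ns
from thermokinesis import orientation_markov as om


@pytest.fixture(scope="module")
def presets_pair():
    return ns.reference_presets()


def _flat_params(params):
    """Temperature-independent copy (all anchors at the overall mean)."""
    return {
        k: ns.DecomposedParameter(
            v.name, v.xbar_temps, np.full(5, float(v.xbar_values.mean())), v.y_cdf, v.eps_cdf
        )
        for k, v in params.items()
    }


class TestMultipliers:
    def test_gamma_multiplier_mean_one(self, rng):
        y = ns.GammaMultiplier(8.0)
        draws = y.rvs(100000, rng)
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        eps = ns.GammaMultiplier(4.0)
        assert eps.rvs(100000, rng).mean() == pytest.approx(1.0, abs=0.02)

    def test_weighted_ecdf_round_trip(self, rng):
        values = rng.gamma(5, 0.2, 5000)
        cdf = ns.WeightedEmpiricalCdf(values)
        draws = cdf.ppf(rng.random(20000))
        assert stats.ks_2samp(values, draws).pvalue > 0.01

    def test_degenerate_cdf(self):
        cdf = ns.DegenerateCdf()
        np.testing.assert_array_equal(cdf.ppf(np.linspace(0, 1, 5)), 1.0)


class TestCopulaModel:
    def test_non_symmetric_rejected(self):
        bad = np.eye(5)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            ns.CopulaModel(corr=bad)

    def test_psd_repair(self):
        # mildly inconsistent triple (0.8, 0.8, 0.2) -> small negative eigenvalue
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = 0.8
        corr[1, 2] = corr[2, 1] = 0.8
        corr[0, 2] = corr[2, 0] = 0.2
        assert np.linalg.eigvalsh(corr).min() < 0
        model = ns.CopulaModel(corr=corr)
        assert np.linalg.eigvalsh(model.corr).min() >= 0
        np.testing.assert_allclose(np.diag(model.corr), 1.0)

    def test_far_from_psd_rejected(self):
        corr = np.eye(5)
        corr[0, 1] = corr[1, 0] = 0.9
        corr[1, 2] = corr[2, 1] = 0.9
        corr[0, 2] = corr[2, 0] = -0.9
        with pytest.raises(ValueError, match="PSD"):
            ns.CopulaModel(corr=corr)

    def test_default_corr_is_psd(self, presets_pair):
        _, copula = presets_pair
        assert np.linalg.eigvalsh(copula.corr).min() >= 0


class TestSampleTrajectoryMeans:
    def test_identity_corr_uncorrelated(self, presets_pair, rng):
        params, _ = presets_pair
        copula = ns.CopulaModel(corr=np.eye(5))
        n = 4000
        draws = ns.sample_trajectory_means(n, params, copula, 26.0, rng)
        corr = np.corrcoef(draws[list(ns.COPULA_PARAMS)].to_numpy(), rowvar=False)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(n) + 0.02)

    def test_strong_coupling_recovered(self, presets_pair, rng):
        """corr 0.9 between disp and p_turn -> rank correlation ~ 0.9."""
        params, _ = presets_pair
        corr = np.eye(5)
        corr[1, 3] = corr[3, 1] = 0.9  # disp vs p_turn
        copula = ns.CopulaModel(corr=corr)
        draws = ns.sample_trajectory_means(10000, params, copula, 26.0, rng)
        rho = stats.spearmanr(draws["disp"], draws["p_turn"]).statistic
        # Gaussian-copula rank correlation: (6 / pi) asin(rho / 2)
        assert rho == pytest.approx(6 / np.pi * np.arcsin(0.9 / 2), abs=0.05)

    def test_degenerate_y_gives_temperature_mean(self, rng):
        params, copula = ns.reference_presets(trajectory_variability=False)
        draws = ns.sample_trajectory_means(100, params, copula, 18.0, rng)
        np.testing.assert_allclose(draws["ibi"], 1.4)
        np.testing.assert_allclose(draws["p_turn"], 0.3)

    def test_probabilities_clamped(self, presets_pair, rng):
        params, copula = presets_pair
        draws = ns.sample_trajectory_means(5000, params, copula, 33.0, rng)
        assert draws["p_turn"].between(0, 1).all()
        assert draws["p_flip"].between(0, 1).all()

    def test_marginal_fidelity(self, presets_pair, rng):
        """Sampled Y marginals match their target CDFs (KS < 0.02)."""
        params, copula = presets_pair
        draws = ns.sample_trajectory_means(10000, params, copula, 26.0, rng)
        y = draws["disp"].to_numpy() / params["disp"].xbar(26.0)
        target = ns.GammaMultiplier(8.0)
        ks = stats.kstest(y, stats.gamma(8.0, scale=1 / 8.0).cdf)
        assert ks.statistic < 0.02


class TestSimulateBouts:
    def _fixed_means(self, **over):
        means = {
            "ibi": 1.0, "disp": 1.5, "turn_angle": 0.6,
            "fwd_angle": 0.04, "p_turn": 0.5, "p_flip": 0.3,
        }
        means.update(over)
        return means

    def test_ballistic_limit(self, presets_pair, rng):
        """p_turn = 0 and zero forward noise -> a perfectly straight path."""
        params, _ = presets_pair
        means = self._fixed_means(p_turn=0.0, fwd_angle=0.0)
        path = ns.simulate_bouts(means, params, 200, rng)
        assert np.all(path["bout_class"] == "forward")
        np.testing.assert_allclose(path["y"], 0.0, atol=1e-12)
        np.testing.assert_allclose(np.diff(path["heading"]), 0.0, atol=1e-12)
        total = path["displacement"].cumsum().to_numpy()
        np.testing.assert_allclose(path["x"], total)

    def test_memoryless_turn_signs(self, presets_pair, rng):
        """p_flip = 0.5 -> successive turn signs uncorrelated."""
        params, _ = presets_pair
        means = self._fixed_means(p_turn=1.0, p_flip=0.5)
        path = ns.simulate_bouts(means, params, 40000, rng)
        signs = np.sign(path["delta_theta"].to_numpy())
        r = np.corrcoef(signs[:-1], signs[1:])[0, 1]
        assert abs(r) < 0.02

    def test_estimator_generator_closure(self, presets_pair, rng):
        """The inference chain recovers the generating parameters."""
        params, _ = presets_pair
        means = self._fixed_means()
        stats_out = {"p_turn": [], "p_flip": [], "ibi": [], "disp": []}
        for _ in range(60):
            path = ns.simulate_bouts(means, params, 300, rng)
            p_turn = float((path["bout_class"] == "turn").mean())
            seq = om.ternarize(path["delta_theta"].to_numpy())
            stats_out["p_turn"].append(p_turn)
            stats_out["p_flip"].append(om.estimate_p_flip(seq, p_turn).p_flip)
            stats_out["ibi"].append(path["delta_t"].mean())
            stats_out["disp"].append(path["displacement"].mean())
        for key, target in [("p_turn", 0.5), ("p_flip", 0.3), ("ibi", 1.0), ("disp", 1.5)]:
            values = np.array(stats_out[key])
            se = values.std(ddof=1) / np.sqrt(len(values))
            assert abs(values.mean() - target) < 3 * max(se, 0.01), key

    def test_timestamps_accumulate(self, presets_pair, rng):
        params, _ = presets_pair
        path = ns.simulate_bouts(self._fixed_means(), params, 50, rng)
        np.testing.assert_allclose(np.diff(path["t"]), path["delta_t"].to_numpy()[:-1])


class TestDecompose:
    def _bout_table(self, rng, n_temp=2, n_traj=15, n_bouts=150):
        params, copula = ns.reference_presets()
        rows = []
        for temp in (18.0, 26.0, 33.0)[:n_temp]:
            means = ns.sample_trajectory_means(n_traj, params, copula, temp, rng)
            for i in range(n_traj):
                path = ns.simulate_bouts(
                    {k: float(means[k].iloc[i]) for k in means.columns},
                    params, n_bouts, rng,
                )
                path = path.assign(temperature=temp, trajectory=f"{temp}-{i}")
                rows.append(path)
        return pd.concat(rows, ignore_index=True), params, copula

    def test_round_trip_xbar(self, rng):
        table, params, copula = self._bout_table(rng, n_temp=3, n_traj=40, n_bouts=200)
        est_params, est_copula = ns.decompose(table)
        for name in ("ibi", "disp"):
            for temp in (18.0, 26.0, 33.0):
                true = params[name].xbar(temp)
                est = est_params[name].xbar(temp)
                assert est == pytest.approx(true, rel=0.1), (name, temp)

    def test_round_trip_correlation(self, rng):
        table, params, copula = self._bout_table(rng, n_temp=3, n_traj=60, n_bouts=200)
        _, est_copula = ns.decompose(table)
        np.testing.assert_allclose(est_copula.corr, copula.corr, atol=0.25)

    def test_no_trajectory_variability_degenerate_y(self, rng):
        params, copula = ns.reference_presets(trajectory_variability=False)
        rows = []
        for temp in (18.0, 26.0):
            for i in range(12):
                means = ns.sample_trajectory_means(1, params, copula, temp, rng)
                path = ns.simulate_bouts(
                    {k: float(means[k].iloc[0]) for k in means.columns},
                    params, 120, rng,
                ).assign(temperature=temp, trajectory=f"{temp}-{i}")
                rows.append(path)
        est_params, _ = ns.decompose(pd.concat(rows, ignore_index=True))
        q = np.linspace(0.05, 0.95, 19)
        spread = np.ptp(est_params["ibi"].y_cdf.ppf(q))
        assert spread < 0.2  # Y concentrated at 1

    def test_insufficient_trajectories_error(self, rng):
        table, *_ = self._bout_table(rng, n_temp=2, n_traj=5, n_bouts=50)
        with pytest.raises(ValueError, match="trajectories"):
            ns.decompose(table)

    def test_single_temperature_error(self, rng):
        table, *_ = self._bout_table(rng, n_temp=1)
        with pytest.raises(ValueError, match="temperatures"):
            ns.decompose(table)


class TestGradient:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            ns.GradientConfig(L=0.0)

    def test_temperature_map(self):
        cfg = ns.GradientConfig(L=0.1)
        assert cfg.temperature_of(0.0) == 18.0
        assert cfg.temperature_of(100.0) == 33.0
        assert cfg.temperature_of(50.0) == pytest.approx(25.5)

    def test_uniform_occupancy_without_kinesis(self, presets_pair):
        """Temperature-independent parameters -> uniform steady state."""
        params, copula = presets_pair
        flat = _flat_params(params)
        cfg = ns.GradientConfig(L=0.1, n_agents=400, t_max=3000, n_time_bins=200)
        res = ns.simulate_gradient(cfg, flat, copula, seed=21)
        snapshot = res.positions[-1]  # independent across agents
        ks = stats.kstest(snapshot, stats.uniform(0, cfg.L_mm).cdf)
        assert ks.pvalue > 0.01

    def test_thermophobic_drift(self, presets_pair):
        """Reference presets -> the population drifts towards the cold side."""
        params, copula = presets_pair
        cfg = ns.GradientConfig(L=0.1, n_agents=300, t_max=2000, n_time_bins=200)
        res = ns.simulate_gradient(cfg, params, copula, seed=5)
        mt = res.mean_temperature()
        quarter = len(mt) // 4
        assert mt[quarter:2 * quarter].mean() < mt[0] - 0.1
        assert np.nanmin(res.positions) >= 0.0
        assert np.nanmax(res.positions) <= cfg.L_mm

    def test_cold_biased_occupancy(self, presets_pair):
        params, copula = presets_pair
        cfg = ns.GradientConfig(L=0.1, n_agents=400, t_max=4000, n_time_bins=200)
        res = ns.simulate_gradient(cfg, params, copula, seed=9)
        centers, occ = res.occupancy(n_bins=10)
        cold = occ[centers < 23].mean()
        hot = occ[centers > 28].mean()
        assert cold > hot

    def test_deterministic_under_seed(self, presets_pair):
        params, copula = presets_pair
        cfg = ns.GradientConfig(L=0.1, n_agents=50, t_max=500, n_time_bins=50)
        a = ns.simulate_gradient(cfg, params, copula, seed=3)
        b = ns.simulate_gradient(cfg, params, copula, seed=3)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestMsdOrdering:
    def test_msd_msr_ordering_in_temperature(self, presets_pair):
        """Exploration grows with temperature.

        MSD increases monotonically over 18-26 degC where bout speed
        rises; above 26 degC the preset speed plateaus while turning
        keeps increasing, so only hot > cold is asserted there. MSR
        (angular exploration) is monotone across 18/26/33.
        """
        params, copula = presets_pair
        msds, msrs = [], []
        for temp in (18.0, 22.0, 26.0, 33.0):
            trajs = ns.simulate_trajectories(
                temp, 80, 250, params, copula, seed=int(temp)
            )
            paths = [
                {
                    "t": p["t"].to_numpy(),
                    "x": p["x"].to_numpy(),
                    "y": p["y"].to_numpy(),
                    "theta": p["heading"].to_numpy(),
                }
                for p in trajs
            ]
            curve = es.msd_msr(paths, dt=1.0, max_lag=80.0)
            msds.append(np.interp(60.0, curve.lag, curve.msd))
            msrs.append(np.interp(20.0, curve.lag, curve.msr))
        assert msds[0] < msds[1] < msds[2]  # 18 < 22 < 26
        assert msds[3] > msds[0]  # hot exploration exceeds cold
        assert msrs[0] < msrs[2] < msrs[3]  # MSR monotone 18/26/33


def test_reflection_helper():
    x, sign = ns._reflect(np.array([-3.0, 5.0, 103.0]), 0.0, 100.0)
    np.testing.assert_allclose(x, [3.0, 5.0, 97.0])
    np.testing.assert_allclose(sign, [-1.0, 1.0, -1.0])
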