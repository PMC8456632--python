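import itertools

import numpy as np
import pytest
from scipy import stats

from thermokinesis import orientation_markov as om
from thermokinesis import synthetic_data as sd
from thermokinesis.presets import preset_by_name


def two_chain_slope_oracle(p_turn: float, p_flip: float) -> float:
    """Brute-force expectation of <D_{n+1} | D_n = +1> by enumerating the
    nine bout-pair combinations of the two-chain law."""
    # given the previous bout was a left turn (state L), the next bout is:
    #   forward with prob 1 - p_turn (D = 0)
    #   turn with prob p_turn; state flips to R with prob p_flip
    expectation = 0.0
    for is_turn, flipped in itertools.product([True, False], repeat=2):
        p = (p_turn if is_turn else 1 - p_turn) * (p_flip if flipped else 1 - p_flip)
        delta = (-1 if flipped else +1) if is_turn else 0
        expectation += p * delta
    return expectation


def simulate_chain(p_turn, p_flip, n, rng):
    # hidden state flips at every bout w.p. p_flip; turns expose it
    is_turn = rng.random(n) < p_turn
    flips = rng.random(n) < p_flip
    state = rng.choice([-1, 1]) * np.cumprod(np.where(flips, -1, 1))
    return np.where(is_turn, state, 0).astype(int)


class TestTernarize:
    @pytest.mark.parametrize(
        "angle,expected", [(0.5, 1), (-0.5, -1), (0.05, 0), (0.0, 0)]
    )
    def test_mapping(self, angle, expected):
        seq = om.ternarize([angle])
        assert seq.values[0] == expected

    def test_length_preserved(self, rng):
        angles = rng.normal(0, 0.4, 100)
        assert len(om.ternarize(angles)) == 100


class TestEstimatePFlip:
    def test_memoryless_limit(self, rng):
        """p_flip = 0.5 -> slope ~ 0 (memoryless process)."""
        values = simulate_chain(0.5, 0.5, 50000, rng)
        est = om.estimate_p_flip(om.ternarize_values(values), 0.5)
        assert est.slope == pytest.approx(0.0, abs=0.02)
        assert est.p_flip == pytest.approx(0.5, abs=0.02)

    def test_exact_enumeration_slope(self, rng):
        """Slope matches the brute-force oracle p_turn (1 - 2 p_flip)."""
        p_turn, p_flip = 0.5, 0.25
        oracle = two_chain_slope_oracle(p_turn, p_flip)
        assert oracle == pytest.approx(0.25)
        values = simulate_chain(p_turn, p_flip, 200000, rng)
        est = om.estimate_p_flip(om.ternarize_values(values), p_turn)
        assert est.slope == pytest.approx(oracle, abs=0.015)

    def test_18c_preset_batch(self, rng):
        """Batch-mean estimate near 0.22 with the 18 degC preset."""
        preset = preset_by_name("18C")
        estimates = []
        for _ in range(100):
            bouts = sd.generate_bout_sequence(preset, n_bouts=200, rng=rng)
            seq = om.ternarize(bouts.delta_theta.to_numpy())
            p_turn = float(np.mean(seq.values != 0))
            estimates.append(om.estimate_p_flip(seq, p_turn).p_flip)
        sem = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.22) < 3 * max(sem, 0.005)

    def test_zero_p_turn_error(self):
        with pytest.raises(ValueError):
            om.estimate_p_flip(om.ternarize_values(np.array([1, -1, 1])), 0.0)

    def test_slope_closure_on_grid(self, rng):
        """Eq-closure property: measured slope = p_turn (1 - 2 p_flip)
        within 3 s.e. on a 5x5 parameter grid."""
        n = 30000
        for p_turn in (0.2, 0.35, 0.5, 0.65, 0.8):
            for p_flip in (0.1, 0.25, 0.5, 0.75, 0.9):
                reps = [
                    om.estimate_p_flip(
                        om.ternarize_values(simulate_chain(p_turn, p_flip, n, rng)),
                        p_turn,
                    ).slope
                    for _ in range(4)
                ]
                expected = p_turn * (1 - 2 * p_flip)
                se = max(np.std(reps, ddof=1) / 2, 1e-3)
                assert abs(np.mean(reps) - expected) < max(3 * se, 0.02)


class TestReconstructSignal:
    def test_two_switch_case(self):
        seq = om.TernarySequence(values=[1, -1], times=[1.0, 5.0])
        sig = om.reconstruct_orientation_signal(seq, dt_grid=0.1, t_start=0.0, t_end=8.0)
        assert np.all(sig.state[sig.t_grid < 5.0] == 1)
        assert np.all(sig.state[sig.t_grid >= 5.0] == -1)

    def test_forwards_transparent(self):
        seq = om.TernarySequence(values=[1, 0, 0, 1, -1], times=[0, 1, 2, 3, 4.0])
        sig = om.reconstruct_orientation_signal(seq, dt_grid=0.5)
        switches = np.flatnonzero(np.diff(sig.state) != 0)
        assert len(switches) == 1
        assert sig.t_grid[switches[0] + 1] == pytest.approx(4.0)

    def test_single_turn_constant(self):
        seq = om.TernarySequence(values=[0, 1, 0], times=[0.0, 1.0, 2.0])
        sig = om.reconstruct_orientation_signal(seq, dt_grid=0.1)
        assert np.all(sig.state == 1)

    def test_no_turns_error(self):
        seq = om.TernarySequence(values=[0, 0], times=[0.0, 1.0])
        with pytest.raises(om.DegenerateSignalError):
            om.reconstruct_orientation_signal(seq)


def simulate_telegraph(k, duration, dt, rng):
    n = int(duration / dt)
    flips = rng.random(n) < k * dt
    return rng.choice([-1, 1]) * np.cumprod(np.where(flips, -1, 1))


class TestAcfAndKFlip:
    def test_acf_starts_at_one(self, rng):
        state = simulate_telegraph(0.3, 200.0, 0.1, rng)
        sig = om.OrientationSignal(t_grid=np.arange(len(state)) * 0.1, state=state)
        lags, acf = om.acf_orientation(sig, max_lag=10.0)
        assert acf[0] == pytest.approx(1.0)
        assert lags[0] == 0.0

    def test_constant_signal_flagged(self):
        sig = om.OrientationSignal(t_grid=np.arange(100) * 0.1, state=np.ones(100, int))
        with pytest.raises(om.DegenerateSignalError):
            om.acf_orientation(sig, max_lag=2.0)

    def test_max_lag_validation(self):
        sig = om.OrientationSignal(t_grid=np.arange(100) * 0.1, state=np.ones(100, int))
        with pytest.raises(ValueError):
            om.acf_orientation(sig, max_lag=50.0)

    def test_telegraph_acf_closed_form(self, rng):
        """Telegraph ACF ~ exp(-2 k t) (closed-form oracle)."""
        k, dt = 0.2, 0.05
        acfs = []
        for _ in range(60):
            state = simulate_telegraph(k, 400.0, dt, rng)
            sig = om.OrientationSignal(t_grid=np.arange(len(state)) * dt, state=state)
            _, acf = om.acf_orientation(sig, max_lag=6.0)
            acfs.append(acf)
        lags = np.arange(len(acfs[0])) * dt
        mean = om.mean_acf(acfs)
        np.testing.assert_allclose(mean, np.exp(-2 * k * lags), atol=0.05)

    def test_fit_k_exact_input(self):
        lags = np.arange(0, 10, 0.1)
        k, (lo, hi) = om.fit_k_flip(lags, np.exp(-0.4 * lags))
        assert k == pytest.approx(0.2, rel=1e-6)
        assert lo <= 0.2 <= hi

    def test_fit_k_on_telegraph_simulation(self, rng):
        k_true, dt = 0.3, 0.05
        acfs = []
        for _ in range(100):
            state = simulate_telegraph(k_true, 300.0, dt, rng)
            sig = om.OrientationSignal(t_grid=np.arange(len(state)) * dt, state=state)
            _, acf = om.acf_orientation(sig, max_lag=5.0)
            acfs.append(acf)
        lags = np.arange(len(acfs[0])) * dt
        k_hat, _ = om.fit_k_flip(lags, om.mean_acf(acfs), fit_window=4.0)
        assert k_hat == pytest.approx(k_true, rel=0.1)

    def test_non_positive_acf_error(self):
        lags = np.arange(0, 5, 0.1)
        acf = np.concatenate([[1.0], -np.ones(len(lags) - 1)])
        with pytest.raises(RuntimeError):
            om.fit_k_flip(lags, acf)


class TestDwellTimes:
    def test_reconstructed_dwell_times_exponential(self, rng):
        """Dwell times of the reconstructed state are exponential.

        With every bout a turn the reconstruction equals the hidden
        state, whose dwell is a geometric number of exponential interbout
        gaps -- exactly exponential (KS test, n = 10^4).
        """
        p_turn, p_flip, mean_ibi = 1.0, 0.3, 1.0
        dwells = []
        while len(dwells) < 10000:
            values = simulate_chain(p_turn, p_flip, 5000, rng)
            times = np.cumsum(rng.exponential(mean_ibi, 5000))
            seq = om.TernarySequence(values=values, times=times)
            turn_t = seq.times[seq.values != 0]
            turn_s = seq.values[seq.values != 0]
            switch_times = turn_t[np.flatnonzero(np.diff(turn_s) != 0) + 1]
            dwells.extend(np.diff(switch_times))
        dwells = np.array(dwells[:10000])
        result = stats.kstest(dwells, stats.expon(scale=dwells.mean()).cdf)
        assert result.pvalue > 0.01

    def test_k_flip_ratio_consistency(self, rng):
        """k from the ACF fit ~ p_flip / <dt> on synthetic batches.

        The approximation is accurate when turns are frequent enough to
        expose most hidden flips, so use the warm-water regime.
        """
        p_turn, p_flip, mean_ibi = 0.8, 0.2, 1.0
        acfs, p_flips = [], []
        for _ in range(150):
            values = simulate_chain(p_turn, p_flip, 400, rng)
            times = np.cumsum(rng.exponential(mean_ibi, 400))
            seq = om.TernarySequence(values=values, times=times)
            p_flips.append(om.estimate_p_flip(seq, p_turn).p_flip)
            sig = om.reconstruct_orientation_signal(seq, dt_grid=0.1)
            _, acf = om.acf_orientation(sig, max_lag=8.0)
            acfs.append(acf)
        lags = np.arange(len(acfs[0])) * 0.1
        k_acf, _ = om.fit_k_flip(lags, om.mean_acf(acfs), fit_window=6.0)
        k_ratio = np.mean(p_flips) / mean_ibi
        assert k_acf == pytest.approx(k_ratio, rel=0.15)


def test_k_flip_monotone_across_presets(rng):
    """Estimated flip rates increase strictly with temperature."""
    k_hats = []
    for label in ("18C", "22C", "26C", "30C", "33C"):
        preset = preset_by_name(label)
        p_flips, ibis = [], []
        for _ in range(60):
            bouts = sd.generate_bout_sequence(preset, n_bouts=300, rng=rng)
            seq = om.ternarize(bouts.delta_theta.to_numpy())
            p_turn = float(np.mean(seq.values != 0))
            p_flips.append(om.estimate_p_flip(seq, p_turn).p_flip)
            ibis.append(bouts.delta_t.mean())
        k_hats.append(np.mean(p_flips) / np.mean(ibis))
    assert all(a < b for a, b in zip(k_hats, k_hats[1:]))
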