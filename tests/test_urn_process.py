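"""Unit tests for the stable-size urn process simulator."""

import numpy as np
import pytest

from stablesize.urn_process import (
    IterationOutcome,
    Mode,
    ProcessConfig,
    UrnState,
    exit_step,
    grow_step,
    initial_state,
    iterate,
    measure_turnover,
    replace_step,
    run,
    shrink_step,
    update_q,
)


def make_state(sizes, q=0.05):
    sizes = np.asarray(sizes, dtype=np.int64)
    return UrnState(sizes, 0, q, int(sizes.sum()))


class TestConfigValidation:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            ProcessConfig(M=0, N0=10, q0=0.05)
        with pytest.raises(ValueError):
            ProcessConfig(M=10, N0=5, q0=0.05)  # N0 < M
        with pytest.raises(ValueError):
            ProcessConfig(M=10, N0=100, q0=1.5)
        with pytest.raises(ValueError):
            ProcessConfig(M=10, N0=100, q0=0.05, delta_exit=0.1, mode="shrink_only")

    def test_mean_size_roundtrip(self):
        config = ProcessConfig.from_mean_size(M=100, E=7.5, q0=0.05)
        assert config.N0 == 750
        assert config.mean_size == 7.5


class TestGrowStep:
    def test_zero_growth_is_impossible_probability(self, rng):
        state = make_state([10] * 5, q=1e-12)
        with pytest.raises(ValueError):
            grow_step(make_state([10] * 5, q=0.0), rng)
        new, gains = grow_step(state, rng)
        assert gains.sum() == 0
        assert np.array_equal(new.sizes, state.sizes)

    def test_binomial_mean_and_variance(self, rng):
        # n=10, q=0.05 over many replicates: mean 0.5, var 0.475
        n_rep = 100_000
        state = make_state([10] * n_rep, q=0.05)
        _, gains = grow_step(state, rng)
        se_mean = np.sqrt(0.475 / n_rep)
        assert abs(gains.mean() - 0.5) < 3 * se_mean
        # var of sample variance ~ 2 var^2 / n for near-normal; be generous
        assert abs(gains.var() - 0.475) < 0.02


class TestShrinkStep:
    def test_no_growth_no_shrink(self, rng):
        state = make_state([5, 5, 5])
        new, losses, delta = shrink_step(state, np.zeros(3, dtype=int), rng)
        assert delta == 0.0
        assert losses.sum() == 0

    def test_printed_delta_formula_at_target(self, rng):
        # N_t = N0 = 10000, sum gains 500 -> delta = 500/10500
        sizes = np.full(1000, 10)
        state = make_state(sizes)
        gains = np.zeros(1000, dtype=int)
        gains[:500] = 1
        state_g = UrnState(state.sizes + gains, 0, 0.05, state.N_t)
        _, _, delta = shrink_step(state_g, gains, rng, N_target=10_000)
        assert delta == pytest.approx(500 / 10_500, rel=1e-12)

    def test_expected_total_restored(self, rng):
        # post-shrink expectation equals the target total
        totals = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            state = make_state(np.full(200, 10))
            state_g, gains = grow_step(state, r)
            state_s, losses, _ = shrink_step(state_g, gains, r, N_target=2000)
            totals.append(state_s.sizes.sum())
        totals = np.asarray(totals)
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - 2000) < 3 * se + 1.0

    def test_disabled_in_exit_only(self, rng):
        state = make_state([5])
        with pytest.raises(ValueError):
            shrink_step(state, np.array([0]), rng, mode=Mode.exit_only)


class TestExitReplace:
    @pytest.mark.parametrize("delta,expect", [(0.0, 0), (1.0, 50)])
    def test_exit_boundaries(self, rng, delta, expect):
        state = make_state([3] * 50)
        _, exited = exit_step(state, delta, rng)
        assert len(exited) == expect

    def test_exit_count_binomial(self, rng):
        M = 10_000
        state = make_state([2] * M)
        _, exited = exit_step(state, 0.1, rng)
        assert abs(len(exited) - 1000) < 3 * np.sqrt(M * 0.1 * 0.9)

    def test_replace_resets_zeros(self):
        state = UrnState(np.array([0, 3, 0, 1]), 0, 0.05, 4)
        new, k = replace_step(state)
        assert k == 2
        assert new.sizes.min() == 1
        assert len(new.sizes) == 4


class TestUpdateQ:
    def test_fixed_point(self):
        config = ProcessConfig(M=100, N0=10_000, q0=0.05)
        assert update_q(10_000, config) == pytest.approx(0.05)

    def test_printed_example(self):
        config = ProcessConfig(M=100, N0=10_000, q0=0.05)
        assert update_q(10_200, config) == pytest.approx(10_500 / 10_200 - 1, rel=1e-12)

    def test_boundary_clamped_with_warning(self):
        config = ProcessConfig(M=100, N0=10_000, q0=0.05)
        with pytest.warns(RuntimeWarning):
            q = update_q(10_500, config)
        assert 0 < q < 1

    def test_degenerate_state(self):
        config = ProcessConfig(M=100, N0=10_000, q0=0.05)
        with pytest.raises(ValueError):
            update_q(0, config)


class TestIterate:
    @pytest.mark.parametrize("mode,delta", [("shrink_only", 0.0), ("exit_only", 0.1), ("mixed", 0.1)])
    def test_urn_count_conserved(self, mode, delta):
        config = ProcessConfig.from_mean_size(
            M=500, E=5.0, q0=0.05, mode=mode, delta_exit=delta, seed=3
        )
        state = initial_state(config)
        r = np.random.default_rng(0)
        for _ in range(20):
            state, outcome = iterate(state, config, r)
            assert len(state.sizes) == 500
            assert state.sizes.min() >= 1
            assert state.N_t == state.sizes.sum()

    def test_martingale_single_iteration(self):
        """E[n_{t+1} | n_t] = n_t for persisting urns (case I)."""
        config = ProcessConfig(M=50_000, N0=50_000 * 20, q0=0.05, mode="shrink_only", seed=5)
        state = UrnState(np.full(50_000, 20), 0, 0.05, 50_000 * 20)
        r = np.random.default_rng(5)
        new, _ = iterate(state, config, r)
        changes = new.sizes - 20
        se = changes.std(ddof=1) / np.sqrt(len(changes))
        assert abs(changes.mean()) < 3 * se + 1e-3


class TestRun:
    def test_seeded_determinism(self):
        config = ProcessConfig.from_mean_size(M=300, E=5.0, q0=0.05, T=30, seed=9)
        a = run(config, collect_pairs=True)
        b = run(config, collect_pairs=True)
        assert np.array_equal(a.size_samples, b.size_samples)
        assert np.array_equal(a.pairs, b.pairs)
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_T_zero_returns_initial_state(self):
        config = ProcessConfig.from_mean_size(M=300, E=5.0, q0=0.05, T=0, seed=9)
        result = run(config)
        assert result.state.t == 0
        assert np.all(result.state.sizes == 5)

    def test_total_fluctuates_around_N0(self, case1_run):
        traj = case1_run.trajectory
        N0 = 2000 * 10
        assert abs(traj[:, 1].mean() / N0 - 1.0) < 0.01

    def test_case1_has_strong_cutoff(self, case1_run):
        from stablesize.fitting import fit_powerlaw_cutoff

        fit = fit_powerlaw_cutoff(case1_run.size_samples, a0=1)
        assert fit.beta_hat > 3 * fit.stderr_beta
        assert fit.alpha_hat < 0.5  # cutoff-dominated, low exponent


class TestTurnover:
    def test_shrink_only_mu_zero(self, case1_run):
        summary = measure_turnover(case1_run.outcomes, case1_run.size_samples)
        assert summary.mu == 0.0

    def test_exit_only_mu_one(self, case2_run):
        summary = measure_turnover(case2_run.outcomes, case2_run.size_samples)
        assert summary.mu == 1.0

    def test_exit_ball_fraction_tracks_exit_rate(self, case2_run):
        # with uniform exits the expected exiting-ball fraction per
        # iteration is delta_exit itself
        summary = measure_turnover(case2_run.outcomes, case2_run.size_samples)
        assert summary.delta_exit_balls == pytest.approx(0.05, rel=0.25)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            measure_turnover([], np.array([1, 2]))
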