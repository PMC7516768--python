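"""Tests for the entropy constraints and the maxent solver."""

import math

import numpy as np
import pytest
from scipy import integrate

from stablesize.entropy_maxent import (
    alpha_from_C,
    binomial_entropy_exact,
    compute_C,
    compute_C_corrected,
    density_moments,
    discrete_pmf,
    entropy_summary,
    normalization_K,
    per_urn_entropy,
    small_n_entropy_ratio,
    solve_alpha_beta,
)


def entropy_by_direct_sum(n, q):
    """Independent oracle: enumerate binomial probabilities explicitly."""
    from math import comb

    total = 0.0
    for k in range(n + 1):
        p = comb(n, k) * q**k * (1 - q) ** (n - k)
        if p > 0:
            total -= p * math.log(p)
    return total


class TestBinomialEntropy:
    @pytest.mark.parametrize(
        "n,q,expected",
        [
            (1, 0.5, math.log(2)),
            (1, 0.1, 0.325083),
            (2, 0.1, 0.525399),  # direct sum: -(0.81 ln .81 + 0.18 ln .18 + 0.01 ln .01)
            (5, 0.0, 0.0),
        ],
    )
    def test_known_values(self, n, q, expected):
        assert binomial_entropy_exact(n, q) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("n", [1, 2, 7, 40])
    @pytest.mark.parametrize("q", [0.02, 0.1, 0.37])
    def test_matches_direct_enumeration(self, n, q):
        assert binomial_entropy_exact(n, q) == pytest.approx(
            entropy_by_direct_sum(n, q), rel=1e-10
        )


class TestSmallNRatio:
    def test_near_0p6_over_wide_q_range(self):
        for q in np.linspace(0.02, 0.2, 10):
            assert 0.55 < small_n_entropy_ratio(q) < 0.65

    @pytest.mark.parametrize("q,expected", [(0.05, 0.599), (0.1, 0.6187)])
    def test_specific_values(self, q, expected):
        assert small_n_entropy_ratio(q) == pytest.approx(expected, abs=1e-3)

    def test_degenerate_q_rejected(self):
        with pytest.raises(ValueError):
            small_n_entropy_ratio(0.0)


class TestPerUrnEntropy:
    def test_quadrupling_size_adds_ln2(self):
        for mode in ("shrink_only", "exit_only"):
            s1 = per_urn_entropy(25, 0.07, mode)
            s4 = per_urn_entropy(100, 0.07, mode)
            assert s4 - s1 == pytest.approx(0.5 * math.log(4), rel=1e-12)

    def test_case_difference_independent_of_n(self):
        d = [
            per_urn_entropy(n, 0.1, "shrink_only") - per_urn_entropy(n, 0.1, "exit_only")
            for n in (3, 30, 300)
        ]
        assert max(d) - min(d) < 1e-12

    def test_matches_exact_binomial_at_large_n(self):
        # case II large-n Gaussian approximation vs exact entropy
        assert per_urn_entropy(100, 0.1, "exit_only") == pytest.approx(
            binomial_entropy_exact(100, 0.1), abs=0.01
        )


class TestEntropyConstraint:
    def test_all_ones_gives_zero(self):
        assert compute_C(np.ones(10)) == 0.0

    def test_printed_example(self):
        assert compute_C([1, 2, 4, 8]) == pytest.approx(6 * math.log(2) / 4)

    def test_permutation_invariance(self, rng):
        sizes = rng.integers(1, 100, 50)
        assert compute_C(sizes) == pytest.approx(compute_C(sizes[::-1]))

    def test_rejects_sizes_below_one(self):
        with pytest.raises(ValueError):
            compute_C([1, 0, 2])

    def test_decreases_under_mean_preserving_spread(self):
        """The geometric mean (hence C) falls as sizes spread at fixed
        arithmetic mean — the mechanism by which turnover raises alpha."""
        base = np.full(100, 10.0)
        spread1 = np.concatenate([np.full(50, 5.0), np.full(50, 15.0)])
        spread2 = np.concatenate([np.full(50, 1.0), np.full(50, 19.0)])
        assert base.mean() == spread1.mean() == spread2.mean()
        assert compute_C(base) > compute_C(spread1) > compute_C(spread2)


class TestCorrectedConstraint:
    def test_equals_raw_without_size_one(self):
        sizes = np.array([2, 3, 4, 10])
        assert compute_C_corrected(sizes, 0.05) == pytest.approx(compute_C(sizes))

    def test_all_size_one(self):
        # every urn contributes ratio * ln 2 instead of ln 1 = 0
        sizes = np.ones(20)
        expected = small_n_entropy_ratio(0.1) * math.log(2)
        assert compute_C_corrected(sizes, 0.1) == pytest.approx(expected)

    def test_never_below_raw(self, rng):
        for _ in range(5):
            sizes = rng.integers(1, 30, 200)
            assert compute_C_corrected(sizes, 0.05) >= compute_C(sizes)

    def test_summary_fields(self, rng):
        sizes = rng.integers(1, 30, 500)
        s = entropy_summary(sizes, 0.05)
        assert s.C_corr >= s.C_raw
        assert 0 <= s.n1_fraction <= 1
        assert 0 < s.ratio_small_n < 1


class TestAlphaFromC:
    @pytest.mark.parametrize(
        "C,a0,expected",
        [(2.0, 1.0, 0.5), (1.0, 1.0, 1.0), (1.0, math.e**0.5, 2.0)],
    )
    def test_closed_form(self, C, a0, expected):
        assert alpha_from_C(C, a0) == pytest.approx(expected)

    def test_infeasible(self):
        with pytest.raises(ValueError):
            alpha_from_C(0.5, math.e)


class TestNormalization:
    @pytest.mark.parametrize("alpha,expected", [(0.5, 0.5), (1.0, 1.0)])
    def test_beta_zero_closed_form(self, alpha, expected):
        assert normalization_K(alpha, 0.0, 1.0) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha,beta", [(0.5, 0.1), (1.5, 0.01), (0.2, 1.0)])
    def test_density_integrates_to_one(self, alpha, beta):
        K = normalization_K(alpha, beta, 1.0)
        val, _ = integrate.quad(
            lambda n: K * n ** -(alpha + 1) * math.exp(-beta * n), 1.0, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_non_normalizable(self):
        with pytest.raises(ValueError):
            normalization_K(-0.5, 0.0, 1.0)


class TestSolver:
    def test_round_trip(self):
        C, E = density_moments(0.8, 0.02, 1.0)
        sol = solve_alpha_beta(C, E, 1.0)
        assert sol.alpha == pytest.approx(0.8, abs=1e-4)
        assert sol.beta == pytest.approx(0.02, abs=1e-4)
        assert abs(sol.implied_C - C) < 1e-6
        assert abs(sol.implied_E - E) < 1e-6 * E

    def test_agrees_with_closed_form_as_beta_vanishes(self):
        # a (C, E) pair generated at tiny beta: solver alpha ~ 1/C
        C, E = density_moments(1.5, 1e-6, 1.0)
        sol = solve_alpha_beta(C, E, 1.0)
        assert sol.alpha == pytest.approx(alpha_from_C(C, 1.0), abs=1e-3)

    def test_monotonicity_alpha_decreases_with_C(self):
        # at fixed mean size, a larger entropy constraint C yields a
        # smaller power-law exponent
        als = [solve_alpha_beta(C, 12.0, 1.0).alpha for C in (1.05, 1.15, 1.3)]
        assert als[0] > als[1] > als[2]

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_alpha_beta(-1.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            solve_alpha_beta(2.0, 0.5, 1.0)


class TestParameterIdentities:
    def test_pareto_mean_log_identity(self, rng):
        """For beta = 0, a0 = 1 the mean log is 1/alpha, so
        alpha_from_C on a large Pareto sample recovers alpha."""
        alpha = 1.25
        u = rng.random(1_000_000)
        samples = u ** (-1.0 / alpha)  # continuous Pareto(alpha) on [1, inf)
        C = float(np.mean(np.log(samples)))
        assert alpha_from_C(C, 1.0) == pytest.approx(alpha, rel=0.02)

    def test_discrete_pmf_normalized(self):
        pmf = discrete_pmf(0.8, 0.01, 1, 10_000)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pmf > 0).all()
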