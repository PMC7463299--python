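"""Grid, sufficient statistics, likelihood, priors, gradient."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import approx_fprime

from skygrid import (
    GMRFSpec,
    GridSpec,
    SkygridState,
    SuffStats,
    build_grid,
    coalescent_loglik,
    extract_event_sequence,
    gmrf_logprior,
    grad_gamma,
    interval_loglik_direct,
    log_posterior,
    sufficient_statistics,
    tau_full_conditional,
    tau_logprior,
)
from skygrid.genealogy import EventSequence

from conftest import random_genealogy


class TestBuildGrid:
    def test_even_spacing(self):
        grid = build_grid(40.0, 4)
        np.testing.assert_allclose(grid.grid_points, [10, 20, 30, 40])
        assert grid.cutoff == 40.0 and grid.n_intervals == 5

    def test_weekly_grid(self):
        grid = build_grid(1.0, 52)
        assert grid.M == 52 and grid.n_intervals == 53
        assert grid.grid_points[-1] == 1.0  # x_M equals the cutoff exactly

    def test_single_point(self):
        grid = build_grid(10.0, 1)
        np.testing.assert_allclose(grid.grid_points, [10.0])
        assert grid.n_intervals == 2

    @pytest.mark.parametrize("cutoff,M", [(0.0, 4), (-1.0, 4), (10.0, 0)])
    def test_invalid_args(self, cutoff, M):
        with pytest.raises(ValueError):
            build_grid(cutoff, M)


def three_tip_sequence():
    """Isochronous 3-tip locus with coalescences at t = 1 and t = 2."""
    return EventSequence(
        times=np.array([0.0, 0.0, 0.0, 1.0, 2.0]),
        kinds=np.array([1, 1, 1, -1, -1]),
        offset=0.0,
        n_tips=3,
    )


class TestSufficientStatistics:
    def test_hand_worked_example(self):
        stats = sufficient_statistics([three_tip_sequence()], GridSpec([1.5]))
        np.testing.assert_allclose(stats.c, [1.0, 1.0])
        np.testing.assert_allclose(stats.S, [3.5, 0.5])

    def test_empty_deep_interval(self):
        stats = sufficient_statistics([three_tip_sequence()], GridSpec([5.0]))
        assert stats.c[1] == 0.0 and stats.S[1] == 0.0

    def test_additive_over_loci(self):
        seq = three_tip_sequence()
        stats = sufficient_statistics([seq, seq], GridSpec([1.5]))
        np.testing.assert_allclose(stats.c, [2.0, 2.0])
        np.testing.assert_allclose(stats.S, [7.0, 1.0])

    def test_boundary_event_goes_to_older_interval(self):
        # coalescence exactly at the grid point x_1 = 1.0
        seq = EventSequence(
            times=np.array([0.0, 0.0, 1.0]),
            kinds=np.array([1, 1, -1]),
            offset=0.0,
            n_tips=2,
        )
        stats = sufficient_statistics([seq], GridSpec([1.0]))
        assert stats.c[0] == 0.0 and stats.c[1] == 1.0
        np.testing.assert_allclose(stats.S, [1.0, 0.0])

    def test_total_coalescent_count(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            gen, grid = random_genealogy(rng)
            seq = extract_event_sequence(gen, gen.most_recent_tip_date)
            stats = sufficient_statistics([seq], grid)
            assert stats.c.sum() == gen.n_tips - 1


class TestCoalescentLoglik:
    def test_worked_value(self, worked_stats):
        assert coalescent_loglik(worked_stats, np.zeros(2)) == pytest.approx(-4.0)

    def test_empty_data(self):
        stats = SuffStats(np.zeros(3), np.zeros(3))
        assert coalescent_loglik(stats, np.ones(3)) == 0.0

    def test_per_interval_mle_value(self, worked_stats):
        gamma = np.log([3.5, 0.5])
        expected = -np.log(3.5) - 1 - np.log(0.5) - 1
        assert coalescent_loglik(worked_stats, gamma) == pytest.approx(expected)

    def test_length_mismatch(self, worked_stats):
        with pytest.raises(ValueError):
            coalescent_loglik(worked_stats, np.zeros(3))

    def test_topology_irrelevant(self):
        """Likelihood depends only on event times, not on which pair merges."""
        from skygrid import assign_tip_dates, parse_newick

        grid = GridSpec([1.5])
        gamma = np.array([0.3, -0.4])
        vals = []
        for nwk in ("((A:1,B:1):1,C:2);", "((A:1,C:1):1,B:2);"):
            dated = assign_tip_dates(
                parse_newick(nwk), {"A": 2000.0, "B": 2000.0, "C": 2000.0}
            )
            seq = extract_event_sequence(dated, 2000.0)
            vals.append(coalescent_loglik(sufficient_statistics([seq], grid), gamma))
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)


class TestDirectLoglikOracle:
    def test_worked_example(self, worked_stats):
        seq = three_tip_sequence()
        grid = GridSpec([1.5])
        direct = interval_loglik_direct(seq, grid, np.zeros(2))
        assert direct == pytest.approx(-4.0)

    def test_single_pair_closed_form(self):
        t = 2.7
        seq = EventSequence(np.array([0.0, 0.0, t]), np.array([1, 1, -1]), 0.0, 2)
        grid = GridSpec([10.0])
        for gamma in (-1.0, 0.0, 1.3):
            g = np.array([gamma, gamma])
            expected = -gamma - t * np.exp(-gamma)
            assert interval_loglik_direct(seq, grid, g) == pytest.approx(expected)

    @settings(deadline=None, max_examples=40)
    @given(seed=st.integers(0, 10**6))
    def test_matches_sufficient_statistic_path(self, seed):
        """The two evaluation routes agree to 1e-10 on random genealogies."""
        rng = np.random.default_rng(seed)
        gen, grid = random_genealogy(rng)
        seq = extract_event_sequence(gen, gen.most_recent_tip_date)
        gamma = rng.normal(0.5, 1.5, grid.n_intervals)
        a = coalescent_loglik(sufficient_statistics([seq], grid), gamma)
        b = interval_loglik_direct(seq, grid, gamma)
        assert b == pytest.approx(a, rel=1e-10, abs=1e-10)


class TestGMRFPrior:
    def test_constant_gamma_null_space(self):
        spec = GMRFSpec(5)
        for tau in (0.5, 1.0, 7.0):
            val = gmrf_logprior(np.full(5, 3.3), tau, spec)
            assert val == pytest.approx(0.5 * spec.M * np.log(tau))

    def test_worked_value(self):
        spec = GMRFSpec(2)
        val = gmrf_logprior(np.array([0.0, 1.0]), 2.0, spec)
        assert val == pytest.approx(0.5 * np.log(2.0) - 1.0)

    @settings(deadline=None, max_examples=100)
    @given(seed=st.integers(0, 10**6))
    def test_quadratic_form_identity(self, seed):
        """gamma' Q gamma equals the sum of squared first differences, and
        is nonnegative with equality only for constant gamma."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        spec = GMRFSpec(n)
        gamma = rng.normal(0, 2, n)
        qf = float(gamma @ spec.Q @ gamma)
        assert qf == pytest.approx(spec.quad_form(gamma), rel=1e-12, abs=1e-12)
        assert qf >= 0
        if np.ptp(gamma) > 1e-12:
            assert qf > 0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            gmrf_logprior(np.zeros(3), 0.0, GMRFSpec(3))


class TestTauPrior:
    def test_default_hyperparameters(self):
        assert tau_logprior(1.0, GMRFSpec(2)) == pytest.approx(-0.001)

    def test_exponential_case(self):
        spec = GMRFSpec(2, a=1.0, b=1.0)
        for tau in (0.2, 1.0, 5.0):
            assert tau_logprior(tau, spec) == pytest.approx(-tau)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            tau_logprior(0.0, GMRFSpec(2))
        with pytest.raises(ValueError):
            tau_logprior(-1.0, GMRFSpec(2))


class TestLogPosterior:
    def test_sum_of_components(self, worked_stats, worked_spec):
        state = SkygridState(np.zeros(2), 1.0)
        assert log_posterior(state, worked_stats, worked_spec) == pytest.approx(-4.001)

    def test_empty_data_reduction(self):
        spec = GMRFSpec(4, a=0.5, b=2.0)
        stats = SuffStats(np.zeros(4), np.zeros(4))
        tau = 1.7
        state = SkygridState(np.full(4, 2.0), tau)
        expected = 0.5 * spec.M * np.log(tau) + (spec.a - 1) * np.log(tau) - spec.b * tau
        assert log_posterior(state, stats, spec) == pytest.approx(expected)

    def test_monotone_in_waiting_times(self, worked_spec):
        state = SkygridState(np.zeros(2), 1.0)
        base = SuffStats(np.array([1.0, 1.0]), np.array([3.5, 0.5]))
        bigger = SuffStats(np.array([1.0, 1.0]), np.array([4.5, 0.5]))
        assert log_posterior(state, bigger, worked_spec) < log_posterior(
            state, base, worked_spec
        )


class TestGradGamma:
    def test_worked_value(self, worked_stats, worked_spec):
        state = SkygridState(np.zeros(2), 1.0)
        np.testing.assert_allclose(
            grad_gamma(state, worked_stats, worked_spec), [2.5, -0.5]
        )

    def test_zero_at_per_interval_mle_without_prior(self):
        stats = SuffStats(np.array([2.0, 3.0]), np.array([5.0, 1.5]))
        gamma = np.log(stats.S / stats.c)
        # tau -> 0 limit: only the likelihood part remains
        g = -stats.c + stats.S * np.exp(-gamma)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10**6))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        spec = GMRFSpec(n)
        stats = SuffStats(
            rng.integers(0, 10, n).astype(float), rng.uniform(0.1, 10, n)
        )
        state = SkygridState(rng.normal(0, 1, n), float(rng.uniform(0.1, 5)))
        analytic = grad_gamma(state, stats, spec)
        numeric = approx_fprime(
            state.gamma,
            lambda g: log_posterior(SkygridState(g, state.tau), stats, spec),
            1e-7,
        )
        np.testing.assert_allclose(analytic, numeric, rtol=1e-5, atol=1e-5)


class TestTauFullConditional:
    def test_constant_gamma(self):
        spec = GMRFSpec(4, a=0.3, b=0.7)
        shape, rate = tau_full_conditional(np.full(4, 1.2), spec)
        assert shape == pytest.approx(0.3 + 1.5)
        assert rate == pytest.approx(0.7)

    def test_worked_value(self):
        spec = GMRFSpec(2)
        shape, rate = tau_full_conditional(np.array([0.0, 1.0]), spec)
        assert shape == pytest.approx(0.501)
        assert rate == pytest.approx(0.501)


class TestGridRefinement:
    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10**6))
    def test_splitting_an_interval_preserves_likelihood(self, seed):
        """Refining the grid and duplicating the matching gamma value leaves
        the coalescent likelihood unchanged."""
        rng = np.random.default_rng(seed)
        gen, grid = random_genealogy(rng)
        seq = extract_event_sequence(gen, gen.most_recent_tip_date)
        gamma = rng.normal(0.5, 1.0, grid.n_intervals)
        base = coalescent_loglik(sufficient_statistics([seq], grid), gamma)
        # split interval k (the one in [x_{k-1}, x_k)) by inserting a point
        k = int(rng.integers(0, grid.M))
        left = 0.0 if k == 0 else grid.grid_points[k - 1]
        new_pt = 0.5 * (left + grid.grid_points[k])
        refined = GridSpec(np.insert(grid.grid_points, k, new_pt))
        gamma_ref = np.insert(gamma, k, gamma[k])
        refined_val = coalescent_loglik(
            sufficient_statistics([seq], refined), gamma_ref
        )
        assert refined_val == pytest.approx(base, rel=1e-10, abs=1e-10)
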