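import numpy as np
import pytest

from limits import (
    AbundanceTimeseries,
    LimitsConfig,
    NoiseSpec,
    build_regression,
    estimate_equilibrium,
    forward_stepwise,
    least_squares,
    limits_infer,
    simulate,
    to_relative,
)
from limits.limits_core import EmptyProblemError, RegressionProblem


class TestEstimateEquilibrium:
    def test_constant_series(self):
        ts = AbundanceTimeseries(values=np.full((3, 10, 2), 4.0))
        np.testing.assert_array_equal(estimate_equilibrium(ts), 4.0)

    def test_odd_count_median(self):
        ts = AbundanceTimeseries(values=np.array([[1.0, 2.0, 3.0]])[:, :, None])
        assert estimate_equilibrium(ts)[0] == 2.0

    def test_long_noisy_simulation_recovers_equilibrium(self, random_model):
        ts = simulate(random_model, T=5000, noise=NoiseSpec(0.05), seed=3)
        est = estimate_equilibrium(ts)
        np.testing.assert_allclose(est, random_model.equilibrium, rtol=0.05)


class TestBuildRegression:
    def test_pinned_at_equilibrium_gives_zero_problem(self, two_species):
        x0 = np.repeat(two_species.equilibrium[:, None], 1, axis=1)
        ts = simulate(two_species, T=10, noise=NoiseSpec(0, 0), initial=x0, seed=0)
        prob = build_regression(ts, 0, two_species.equilibrium)
        np.testing.assert_allclose(prob.design, 0.0, atol=1e-12)
        np.testing.assert_allclose(prob.response, 0.0, atol=1e-12)

    def test_zero_abundance_transitions_dropped(self):
        # focal trajectory [1, 0, 1, 1]: only the final transition survives
        values = np.array([[1.0, 0.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0]])[:, :, None]
        ts = AbundanceTimeseries(values=values)
        prob = build_regression(ts, 0, np.array([1.0, 1.0]))
        assert prob.n_rows == 1
        assert prob.kept_rows == [(0, 2)]

    def test_rows_never_cross_replicate_boundaries(self, rng):
        vals = rng.uniform(0.5, 2.0, size=(2, 6, 3))
        ts = AbundanceTimeseries(values=vals)
        prob = build_regression(ts, 0, np.ones(2))
        assert prob.n_rows == 3 * 5
        assert all(t < 5 for _, t in prob.kept_rows)

    def test_all_zero_focal_raises(self):
        vals = np.ones((2, 4, 1))
        vals[0] = 0.0
        with pytest.raises(EmptyProblemError):
            build_regression(AbundanceTimeseries(values=vals), 0, np.ones(2))

    def test_noiseless_two_species_exactly_identifiable(self, two_species):
        ts = simulate(two_species, T=200, R=3, noise=NoiseSpec(0, 0), seed=4)
        for focal in range(2):
            prob = build_regression(ts, focal, two_species.equilibrium)
            row = least_squares(prob, [0, 1])
            np.testing.assert_allclose(
                row, two_species.coefficients[focal], rtol=1e-6, atol=1e-9
            )


class TestLeastSquares:
    def test_noiseless_univariate_coefficient(self, rng):
        design = rng.normal(size=(20, 3))
        prob = RegressionProblem(design=design, response=2.0 * design[:, 1], focal_index=1)
        row = least_squares(prob, [1])
        assert row[1] == pytest.approx(2.0, rel=1e-12)
        assert row[0] == row[2] == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        design = rng.normal(size=(50, 4))
        response = rng.normal(size=50)
        prob = RegressionProblem(design=design, response=response, focal_index=0)
        row = least_squares(prob, [0, 1, 2, 3])
        oracle = np.linalg.solve(design.T @ design, design.T @ response)
        np.testing.assert_allclose(row, oracle, atol=1e-10)

    def test_duplicated_column_gives_minimum_norm_solution(self, rng):
        col = rng.normal(size=30)
        design = np.column_stack([col, col, rng.normal(size=30)])
        prob = RegressionProblem(design=design, response=3.0 * col, focal_index=0)
        row = least_squares(prob, [0, 1])
        assert np.all(np.isfinite(row))
        # min-norm splits the coefficient evenly across the duplicates
        assert row[0] == pytest.approx(row[1], rel=1e-10)
        assert row[0] + row[1] == pytest.approx(3.0, rel=1e-10)


class TestForwardStepwise:
    def test_huge_threshold_keeps_only_diagonal(self, noisy_series, random_model):
        prob = build_regression(noisy_series, 2, random_model.equilibrium)
        rows = np.arange(prob.n_rows)
        row = forward_stepwise(prob, rows[::2], rows[1::2], threshold=1.0)
        assert np.count_nonzero(row) == 1
        assert row[2] != 0

    def test_recovers_true_support_on_noiseless_chain(self, chain_model):
        ts = simulate(chain_model, T=300, R=2, noise=NoiseSpec(0, 0), seed=5)
        for focal in range(3):
            prob = build_regression(ts, focal, chain_model.equilibrium)
            rows = np.arange(prob.n_rows)
            row = forward_stepwise(prob, rows[::2], rows[1::2], threshold=0.05)
            true_support = set(np.flatnonzero(chain_model.coefficients[focal]))
            assert set(np.flatnonzero(row)) == true_support

    def test_tie_broken_by_lowest_index(self, rng):
        # columns 1 and 2 identical: candidate scan must pick index 1
        col = rng.normal(size=40)
        noise = rng.normal(size=40)
        design = np.column_stack([rng.normal(size=40), col, col])
        prob = RegressionProblem(
            design=design, response=design[:, 0] + col + 0.01 * noise, focal_index=0
        )
        rows = np.arange(40)
        row = forward_stepwise(prob, rows[:20], rows[20:], threshold=0.0)
        assert row[1] != 0.0
        assert row[2] == 0.0

    def test_perfect_initial_fit_returns_immediately(self, rng):
        design = rng.normal(size=(20, 2))
        prob = RegressionProblem(design=design, response=design[:, 0], focal_index=0)
        rows = np.arange(20)
        row = forward_stepwise(prob, rows[:10], rows[10:], threshold=0.05)
        assert row[0] == pytest.approx(1.0, rel=1e-10)
        assert row[1] == 0.0

    def test_overlapping_partitions_rejected(self, rng):
        design = rng.normal(size=(10, 2))
        prob = RegressionProblem(design=design, response=design[:, 0], focal_index=0)
        with pytest.raises(ValueError, match="disjoint"):
            forward_stepwise(prob, [0, 1, 2], [2, 3, 4], threshold=0.0)


class TestLimitsInfer:
    def test_single_bootstrap_equals_single_stepwise_fit(self, noisy_series, random_model):
        config = LimitsConfig(threshold=0.05, n_bootstrap=1, seed=10)
        net = limits_infer(noisy_series, config)
        xbar = estimate_equilibrium(noisy_series)
        rng = np.random.default_rng(10)
        for i in range(10):
            prob = build_regression(noisy_series, i, xbar)
            k = prob.n_rows
            perm = rng.permutation(k)
            n_train = k - k // 2
            expected = forward_stepwise(
                prob, perm[:n_train], perm[n_train:], threshold=0.05
            )
            np.testing.assert_array_equal(net.coefficients[i], expected)

    def test_median_preserves_majority_zeros(self):
        stack = np.array([0.0, 0.0, 5.0])
        assert np.median(stack) == 0.0  # the aggregation rule the field relies on

    def test_determinism(self, noisy_series):
        config = LimitsConfig(threshold=0.05, n_bootstrap=10, seed=3)
        a = limits_infer(noisy_series, config)
        b = limits_infer(noisy_series, config)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_diagonal_always_active(self, noisy_series):
        net = limits_infer(noisy_series, LimitsConfig(threshold=0.05, n_bootstrap=5, seed=1))
        assert np.all(np.diag(net.coefficients) != 0)

    def test_sparsity_bounded_by_largest_active_set(self, noisy_series):
        net = limits_infer(noisy_series, LimitsConfig(threshold=0.05, n_bootstrap=9, seed=2))
        for i in range(net.n_species):
            per_fit = np.count_nonzero(net.per_bootstrap[:, i, :], axis=1)
            assert np.count_nonzero(net.coefficients[i]) <= per_fit.max()

    def test_huge_threshold_gives_diagonal_network(self, noisy_series):
        net = limits_infer(noisy_series, LimitsConfig(threshold=10.0, n_bootstrap=5, seed=1))
        off = net.coefficients[~np.eye(10, dtype=bool)]
        assert np.all(off == 0)

    def test_species_without_transitions_gets_zero_row(self):
        vals = np.ones((3, 30, 1)) + 0.1 * np.random.default_rng(0).normal(size=(3, 30, 1))
        vals = np.abs(vals)
        vals[1] = 0.0  # never observed
        ts = AbundanceTimeseries(values=vals)
        net = limits_infer(ts, LimitsConfig(threshold=0.05, n_bootstrap=3, seed=0))
        assert np.all(net.coefficients[1] == 0)

    def test_absolute_and_relative_fits_are_proportional(self, noisy_series):
        """Compositional data recovers coefficients up to one global scale
        (total abundance fluctuations are small for a 10-species community)."""
        cfg = LimitsConfig(threshold=0.05, n_bootstrap=25, seed=1)
        net_abs = limits_infer(noisy_series, cfg)
        net_rel = limits_infer(to_relative(noisy_series), cfg)
        a = net_abs.coefficients.ravel()
        b = net_rel.coefficients.ravel()
        corr = np.corrcoef(a, b)[0, 1]
        assert corr > 0.95


def test_parameter_recovery_on_random_communities(recovery_panel):
    """Median squared correlation between true and inferred coefficients is
    high across 20 random stable 10-species communities."""
    r2 = [r for _, _, _, r in recovery_panel]
    assert np.median(r2) >= 0.8


def test_bagging_reduces_estimator_variance(random_model):
    """Across data re-draws, median-bagged coefficients vary less than
    single-partition fits at 10% measurement noise."""
    from limits import add_measurement_noise

    bagged, single = [], []
    for draw in range(6):
        ts = simulate(random_model, T=250, R=4, noise=NoiseSpec(0.05), seed=100 + draw)
        obs = add_measurement_noise(to_relative(ts), 0.10, seed=200 + draw)
        bagged.append(
            limits_infer(obs, LimitsConfig(threshold=0.03, n_bootstrap=51, seed=1)).coefficients
        )
        single.append(
            limits_infer(obs, LimitsConfig(threshold=0.03, n_bootstrap=1, seed=1)).coefficients
        )
    var_bagged = np.var(np.stack(bagged), axis=0).mean()
    var_single = np.var(np.stack(single), axis=0).mean()
    assert var_bagged < var_single
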