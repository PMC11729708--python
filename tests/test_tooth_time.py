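import numpy as np
import pytest

from weanling import synthetic, tooth_time
from weanling.tooth_time import (
    AgeGrid,
    GrowthModel,
    assign_increment_ages,
    build_overlap_matrix,
    fit_temporal_model,
)


class TestGrowthModel:
    def test_piecewise_interpolation(self):
        g = GrowthModel(((0.0, 0.25), (0.4, 3.0), (1.0, 9.5)))
        # hand interpolation on the first linear piece
        assert g.age_at(0.2) == pytest.approx(1.625)
        assert g.age_at(0.4) == pytest.approx(3.0)
        assert g.age_at(0.0) == pytest.approx(0.25)
        assert g.age_at(1.0) == pytest.approx(9.5)

    @pytest.mark.parametrize(
        "points",
        [
            ((0.0, 0.25),),  # too few
            ((0.1, 0.25), (1.0, 9.5)),  # does not start at 0
            ((0.0, 0.25), (0.5, 3.0), (0.4, 9.5)),  # positions not increasing
            ((0.0, 3.0), (1.0, 0.25)),  # ages not increasing
        ],
    )
    def test_invalid_control_points(self, points):
        with pytest.raises(ValueError):
            GrowthModel(points)


class TestAssignAges:
    def test_uniform_growth_equal_increments(self):
        """Ten equal slices under uniform growth split 9.25 years evenly."""
        g = GrowthModel(((0.0, 0.25), (1.0, 9.5)))
        truth = synthetic.SyntheticTruth(seed=0, n_increments=10, growth=g)
        df, _ = synthetic.generate_individual(truth)
        aged = assign_increment_ages(df, g)
        assert aged["age_start"].iloc[0] == pytest.approx(0.25)
        assert aged["age_end"].iloc[0] == pytest.approx(1.175)

    def test_interval_starts_strictly_increasing(self, weaning_profile):
        aged = assign_increment_ages(weaning_profile)
        starts = aged["age_start"].to_numpy()
        assert (np.diff(starts) > 0).all()
        # half-open intervals tile the record without overlap
        np.testing.assert_allclose(
            aged["age_end"].to_numpy()[:-1], starts[1:], atol=1e-12
        )

    def test_position_outside_tooth_rejected(self, weaning_profile):
        with pytest.raises(ValueError):
            assign_increment_ages(weaning_profile, total_length_mm=10.0)


class TestOverlapMatrix:
    def test_exact_bin_gives_unit_row(self, default_grid):
        W = build_overlap_matrix(np.array([[0.75, 1.25]]), default_grid)
        assert W[0, 1] == pytest.approx(1.0)
        assert W.sum() == pytest.approx(1.0)

    def test_equal_split_across_two_bins(self):
        grid = AgeGrid(0.5, 1.5, 0.5)
        W = build_overlap_matrix(np.array([[0.5, 1.5]]), grid)
        np.testing.assert_allclose(W[0], [0.5, 0.5])

    def test_rows_sum_to_one_on_random_intervals(self, default_grid):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.25, 9.0, size=1000)
        b = a + rng.uniform(0.05, 2.0, size=1000)
        W = build_overlap_matrix(np.column_stack([a, np.minimum(b, 9.5)]),
                                 default_grid)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)

    def test_interval_outside_grid_rejected(self, default_grid):
        with pytest.raises(ValueError):
            build_overlap_matrix(np.array([[10.0, 11.0]]), default_grid)


class TestAgeGrid:
    def test_bins_constant_half_year_width(self, default_grid):
        widths = np.diff(default_grid.edges)
        np.testing.assert_allclose(widths, 0.5)
        assert default_grid.edges[0] == 0.25
        assert default_grid.edges[-1] >= 9.5


class TestTemporalModel:
    def test_identity_limit_reproduces_measurements(self):
        """One increment per bin with a tight noise prior: the posterior
        must return the raw measurements."""
        grid = AgeGrid(0.25, 1.75, 0.5)
        y = np.array([10.0, 9.0, 8.0])
        tp = fit_temporal_model(y, np.eye(3), seed=1, grid=grid,
                                sigma_scale=0.01)
        assert np.abs(tp.mean - y).max() < 0.05

    def test_constant_series_recovered(self):
        grid = AgeGrid(0.25, 1.75, 0.5)
        tp = fit_temporal_model(np.full(3, 5.0), np.eye(3), seed=2, grid=grid)
        assert np.abs(tp.mean - 5.0).max() < 0.1

    def test_gls_oracle_agreement(self):
        """With fixed hyperparameters the posterior mean must match the
        closed-form Gaussian linear-model solution."""
        rng = np.random.default_rng(0)
        grid = AgeGrid(0.0, 4.0, 0.5)
        iv = np.sort(rng.uniform(0, 4, (5, 2)), axis=1)
        iv[:, 1] = np.minimum(iv[:, 0] + np.maximum(iv[:, 1] - iv[:, 0], 0.3),
                              4.0)
        W = build_overlap_matrix(iv, grid)
        y = rng.normal(10, 1, 5)
        sig, tau = 0.2, 5.0
        tp = fit_temporal_model(y, W, seed=3, grid=grid, fix_sigma=sig,
                                fix_tau=tau)
        n = grid.n_bins
        D = np.diff(np.eye(n), axis=0)
        Q = D.T @ D / tau**2
        Q[0, 0] += 1 / 100.0
        A = Q + W.T @ W / sig**2
        mu = np.linalg.solve(A, Q @ np.full(n, y.mean()) + W.T @ y / sig**2)
        assert np.max(np.abs(tp.mean - mu) / tp.sd) < 3.0

    def test_row_permutation_invariance(self, weaning_profile, default_grid):
        aged = assign_increment_ages(weaning_profile)
        W = build_overlap_matrix(aged[["age_start", "age_end"]].to_numpy(),
                                 default_grid)
        y = aged["d15N"].to_numpy()
        perm = np.random.default_rng(5).permutation(len(y))
        tp1 = fit_temporal_model(y, W, seed=9, grid=default_grid)
        tp2 = fit_temporal_model(y[perm], W[perm], seed=9, grid=default_grid)
        np.testing.assert_allclose(tp1.mean, tp2.mean, atol=1e-9)

    def test_unobserved_bins_flagged_not_imputed(self, default_grid):
        """Bins with no measurement weight carry wide, flagged intervals."""
        iv = np.array([[0.25, 0.75], [0.75, 1.25]])
        W = np.zeros((2, default_grid.n_bins))
        W[:, :2] = build_overlap_matrix(iv, default_grid)[:, :2]
        tp = fit_temporal_model(np.array([10.0, 9.0]), W, seed=4,
                                grid=default_grid)
        assert tp.observed[:2].all() and not tp.observed[2:].any()
        # prior-driven uncertainty exceeds the observed bins' and grows
        # with distance from the data
        assert tp.sd[2:].min() > tp.sd[:2].max()
        assert tp.sd[-1] > 3 * tp.sd[:2].max()

    def test_quantiles_ordered(self, weaning_profile, default_grid):
        aged = assign_increment_ages(weaning_profile)
        W = build_overlap_matrix(aged[["age_start", "age_end"]].to_numpy(),
                                 default_grid)
        tp = fit_temporal_model(aged["d15N"].to_numpy(), W, seed=11,
                                grid=default_grid)
        assert (tp.quantiles[2.5] <= tp.quantiles[16.0]).all()
        assert (tp.quantiles[16.0] <= tp.quantiles[84.0]).all()
        assert (tp.quantiles[84.0] <= tp.quantiles[97.5]).all()
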