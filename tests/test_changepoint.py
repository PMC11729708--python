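import numpy as np
import pandas as pd
import pytest

from weanling import changepoint as cpm
from weanling.changepoint import (
    CessationEstimate,
    InsufficientDataError,
    LooResult,
    SegmentedModelSpec,
    candidate_menu,
    cessation_interval,
    classify_vs_threshold,
    compute_loo,
    estimate_cessation,
    exact_loo,
    fit_segmented_model,
    rank_models,
)


class TestSpecsAndMenu:
    def test_menu_is_the_six_changepoint_candidates(self):
        menu = candidate_menu()
        assert len(menu) == 6
        assert {(s.n_segments, s.first_slope_constrained) for s in menu} == {
            (k, c) for k in (2, 3, 4) for c in (False, True)
        }

    @pytest.mark.parametrize("k, n_params", [(1, 3), (2, 5), (3, 7), (4, 9)])
    def test_parameter_count(self, k, n_params):
        assert SegmentedModelSpec(k).n_params == n_params

    def test_constrained_single_segment_rejected(self):
        with pytest.raises(ValueError):
            SegmentedModelSpec(1, True)


class TestFitSegmentedModel:
    def test_noiseless_line_slope_recovery(self):
        """Single-segment fit against the least-squares oracle."""
        t = np.arange(0.5, 9.5, 0.5)
        y = 12.0 - 1.0 * t
        fit = fit_segmented_model(t, y, SegmentedModelSpec(1), seed=1)
        ols_slope = np.polyfit(t, y, 1)[0]
        assert fit.slopes.mean() == pytest.approx(ols_slope, abs=0.1)

    def test_two_segment_changepoint_recovery_over_seeds(self):
        """Decline to 2.0 y then plateau: the posterior median change
        point lands within half a year of truth (median over 20 seeds)."""
        t = np.arange(0.5, 9.5, 0.5)
        medians = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            y = np.where(t < 2.0, 11.5 - 2.5 / 1.5 * (t - 0.5), 9.0)
            y = y + 0.15 * rng.standard_normal(t.size)
            fit = fit_segmented_model(t, y, SegmentedModelSpec(2), seed=s)
            medians.append(np.median(fit.changepoints))
        assert abs(np.median(medians) - 2.0) < 0.5

    def test_constrained_prior_truncates_first_slope(self, binned_weaning_series):
        t, y = binned_weaning_series
        fit = fit_segmented_model(t, y, SegmentedModelSpec(2, True), seed=2)
        assert (fit.slopes[:, 0] < 0).all()

    def test_changepoints_ordered_within_span(self, binned_weaning_series):
        t, y = binned_weaning_series
        fit = fit_segmented_model(t, y, SegmentedModelSpec(3), seed=3)
        assert (np.diff(fit.changepoints, axis=1) > 0).all()
        assert fit.changepoints.min() > t.min()
        assert fit.changepoints.max() < t.max()

    def test_too_few_bins_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_segmented_model(
                np.array([0.5, 1.0, 1.5]), np.array([10.0, 9.0, 8.0]),
                SegmentedModelSpec(2), seed=0,
            )

    def test_log_likelihood_finite(self, binned_weaning_series):
        t, y = binned_weaning_series
        fit = fit_segmented_model(t, y, SegmentedModelSpec(2), seed=5)
        assert np.isfinite(fit.log_lik).all()


class TestLoo:
    def test_self_comparison_has_zero_diff(self, binned_weaning_series):
        t, y = binned_weaning_series
        spec = SegmentedModelSpec(2)
        l1 = compute_loo(fit_segmented_model(t, y, spec, seed=7))
        l2 = compute_loo(fit_segmented_model(t, y, spec, seed=7))
        assert l1.elpd == l2.elpd  # identical seed, identical fit
        _, table = rank_models([l1, l2])
        assert table["elpd_diff"].abs().max() == 0.0

    def test_psis_matches_exact_refits_on_short_series(self):
        """Importance-sampling LOO against the brute-force refit oracle."""
        t = np.arange(0.5, 4.5, 0.5)
        rng = np.random.default_rng(5)
        y = np.where(t < 2.0, 11.0 - 1.5 * (t - 0.5), 8.75)
        y = y + 0.2 * rng.standard_normal(t.size)
        for spec in (SegmentedModelSpec(2), SegmentedModelSpec(2, True)):
            fit = fit_segmented_model(t, y, spec, seed=3)
            loo = compute_loo(fit)
            exact, _ = exact_loo(t, y, spec, seed=3)
            assert abs(loo.elpd - exact) <= 2 * loo.se

    def test_simpler_truth_scores_at_least_as_well(self):
        """On single-line truth, the 1-segment model's ELPD is not
        meaningfully below the 4-segment model's (>= 90% of 20 seeds)."""
        t = np.arange(0.5, 9.5, 0.5)
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(2000 + s)
            y = 11.0 - 0.5 * t + 0.1 * rng.standard_normal(t.size)
            l1 = compute_loo(
                fit_segmented_model(t, y, SegmentedModelSpec(1), seed=s)
            )
            l4 = compute_loo(
                fit_segmented_model(t, y, SegmentedModelSpec(4), seed=s)
            )
            diff = l1.pointwise - l4.pointwise
            se_diff = np.sqrt(diff.size * np.var(diff, ddof=1))
            wins += l1.elpd >= l4.elpd - 2 * se_diff
        assert wins >= 18


def _loo_result(spec, elpd, pointwise):
    return LooResult(
        spec=spec, elpd=elpd, se=1.0, pointwise=np.asarray(pointwise),
        pareto_k=np.zeros(len(pointwise)),
    )


class TestRankModels:
    def test_single_candidate_selected(self):
        spec = SegmentedModelSpec(2)
        sel, table = rank_models([_loo_result(spec, -3.0, [-1.0, -1.0, -1.0])])
        assert sel == spec
        assert table["selected"].sum() == 1

    def test_parsimony_beats_best_elpd_within_ratio(self):
        """A preserved simpler model wins over the top-ELPD model."""
        rng = np.random.default_rng(0)
        base = rng.normal(-1.0, 0.3, 12)
        # the simpler model scores ~1 nat worse overall, with the deficit
        # spread noisily over observations (ratio ~ 1, well under 5)
        deficit = 1.0 / 12 + rng.normal(0, 0.25, 12)
        best = _loo_result(SegmentedModelSpec(3), float(base.sum() + deficit.sum()),
                           base + deficit)
        simpler = _loo_result(SegmentedModelSpec(2), float(base.sum()), base)
        sel, table = rank_models([best, simpler])
        assert sel.n_segments == 2
        assert not table["excluded"].any()

    def test_large_ratio_excluded_despite_fewest_params(self):
        rng = np.random.default_rng(1)
        base = rng.normal(-1.0, 0.05, 12)
        good = _loo_result(SegmentedModelSpec(4), float(base.sum()), base)
        # uniformly worse by 3 per point: huge diff, tiny paired variance
        bad = _loo_result(SegmentedModelSpec(2), float(base.sum() - 36.0),
                          base - 3.0 + rng.normal(0, 0.01, 12))
        sel, table = rank_models([bad, good])
        assert sel.n_segments == 4
        assert table.loc[table["spec"] == "2seg-u", "excluded"].item()

    def test_invariant_to_candidate_order(self, binned_weaning_series):
        t, y = binned_weaning_series
        loos = [
            compute_loo(fit_segmented_model(t, y, s, seed=11))
            for s in candidate_menu()
        ]
        sel1, _ = rank_models(loos)
        sel2, _ = rank_models(list(reversed(loos)))
        assert sel1 == sel2


class TestCessationInterval:
    def test_rising_series_reports_no_descending_trend(self):
        t = np.arange(0.5, 9.5, 0.5)
        rng = np.random.default_rng(3)
        y = 8.0 + 0.3 * t + 0.1 * rng.standard_normal(t.size)
        est, _ = estimate_cessation(t, y, seed=4)
        assert est.status == "no_descending_trend"
        assert np.isnan(est.median)

    def test_estimated_intervals_nested_and_in_range(self, binned_weaning_series):
        t, y = binned_weaning_series
        est, _ = estimate_cessation(t, y, seed=5)
        assert est.status == "estimated"
        lo68, hi68 = est.ci68
        lo95, hi95 = est.ci95
        assert lo95 <= lo68 <= hi68 <= hi95
        assert t.min() <= lo95 and hi95 <= t.max()

    def test_cessation_ends_initial_descending_run(self):
        """With a nursing plateau before the decline, the cessation change
        point is the one ending the decline, not the first boundary."""
        t = np.arange(0.5, 9.5, 0.5)
        rng = np.random.default_rng(8)
        y = np.where(t < 2.5, 11.5,
                     np.where(t < 5.0, 11.5 - 2.5 * (t - 2.5) / 2.5, 9.0))
        y = y + 0.08 * rng.standard_normal(t.size)
        fit = fit_segmented_model(t, y, SegmentedModelSpec(3, True), seed=6)
        est = cessation_interval(fit)
        assert est.status == "estimated"
        assert est.cessation_cp_index == 1
        assert est.median == pytest.approx(5.0, abs=0.6)


class TestClassifyVsThreshold:
    @pytest.mark.parametrize(
        "ci95, ci68, expected",
        [
            ((2.4, 3.6), (2.7, 3.2), "above"),
            ((1.2, 1.9), (1.4, 1.7), "below"),
            ((1.7, 2.3), (1.8, 2.1), "straddling"),
        ],
    )
    def test_interval_comparison(self, ci95, ci68, expected):
        est = CessationEstimate(
            status="estimated", median=np.mean(ci68), ci68=ci68, ci95=ci95
        )
        assert classify_vs_threshold(est, 2.0) == expected

    def test_unestimated_is_none(self):
        est = CessationEstimate(status="no_descending_trend")
        assert classify_vs_threshold(est) == "none"
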