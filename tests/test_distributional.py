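"""Quantile functions, TD objects and L-moments (both estimators)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sotdr.actigraphy_io import MINUTES_PER_DAY
from sotdr.distributional import (
    build_td_object,
    default_p_grid,
    empirical_cdf,
    estimate_quantile_function,
    lmoments_from_quantile,
    quantile_integral_mean,
    reconstruct_quantile_from_lmoments,
    sample_lmoments_ustat,
    td_overall_mean,
    time_varying_lmoments,
)
from sotdr.actigraphy_io import aggregate_to_epochs

from conftest import make_panel


def type6_oracle(sample, p):
    """Direct evaluation of the order-statistic interpolation formula."""
    x = np.sort(np.asarray(sample, float))
    n = x.size
    g = (n + 1) * p
    k = int(np.floor(g))
    w = g - k
    if k < 1:
        return x[0]
    if k >= n:
        return x[-1]
    return (1 - w) * x[k - 1] + w * x[k]


class TestEmpiricalCDF:
    def test_counts(self):
        assert empirical_cdf([1, 2, 3], 2) == pytest.approx(2 / 3)
        assert empirical_cdf([1, 2, 3], 0.5) == 0.0
        assert empirical_cdf([1, 2, 3], 3) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_cdf([], 1.0)


class TestQuantileEstimator:
    def test_constant_sample(self):
        qf = estimate_quantile_function([5, 5, 5, 5])
        assert np.allclose(qf.values, 5.0)

    def test_printed_formula_cases(self):
        qf = estimate_quantile_function([10, 20, 30, 40], p_grid=[0.5])
        assert qf.values[0] == pytest.approx(25.0)   # (n+1)p = 2.5, w = .5
        qf = estimate_quantile_function([3, 1, 2], p_grid=[0.25])
        assert qf.values[0] == pytest.approx(1.0)    # (n+1)p = 1, w = 0

    def test_exact_at_plotting_positions(self, rng):
        x = rng.lognormal(0, 1, 17)
        n = x.size
        xs = np.sort(x)
        ks = np.arange(1, n + 1)
        qf = estimate_quantile_function(x, p_grid=ks / (n + 1))
        assert np.allclose(qf.values, xs)

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(0, 1e4), min_size=2, max_size=60),
           st.integers(0, 1000))
    def test_matches_oracle_and_monotone(self, sample, seed):
        p_grid = default_p_grid()
        qf = estimate_quantile_function(sample, p_grid)
        assert np.all(np.diff(qf.values) >= -1e-9)
        r = np.random.default_rng(seed)
        for p in r.choice(p_grid, size=5):
            assert qf.values[np.searchsorted(p_grid, p)] == pytest.approx(
                type6_oracle(sample, p))

    def test_nan_policy(self):
        with pytest.raises(ValueError):
            estimate_quantile_function([1.0, np.nan])
        qf = estimate_quantile_function([1.0, np.nan, 3.0], drop_missing=True)
        assert qf.sample_size == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_quantile_function([])


class TestTDObject:
    def test_constant_panel(self, constant_panel):
        td = build_td_object(constant_panel)
        assert td.Q.shape == (144, 99)
        assert np.allclose(td.Q, 7.5)
        assert np.all(td.pooled_sizes == 20)   # 10 minutes x 2 days

    def test_windowed_median_by_interpolation_rule(self):
        vals = np.full(MINUTES_PER_DAY, np.nan)
        window = [10, 20, 30, 40, 10, 20, 30, 40, 10, 20]
        vals[:10] = window
        # only the first epoch is observed; pooled sample = the 10 values
        td = build_td_object(make_panel(np.nan_to_num(vals[None, :], nan=0.0)))
        med = td.Q[0, td.p_grid.tolist().index(0.5)]
        assert med == pytest.approx(type6_oracle(window, 0.5))
        assert med == pytest.approx(20.0)

    def test_default_epoch_structure(self, rng):
        panel = make_panel(rng.gamma(1, 5, (3, MINUTES_PER_DAY)))
        td = build_td_object(panel)  # h = 5 -> 144 epochs
        assert td.t_grid.size == 144
        assert np.all(td.pooled_sizes == 10 * 3)

    def test_rows_monotone(self, rng):
        panel = make_panel(rng.lognormal(0, 1, (2, MINUTES_PER_DAY)))
        td = build_td_object(panel)
        assert np.all(np.diff(td.Q, axis=1) >= -1e-9)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            build_td_object(make_panel(np.full((1, MINUTES_PER_DAY), np.nan)))


class TestLMomentsUstat:
    def test_order1_is_mean(self):
        assert sample_lmoments_ustat([1, 2, 3], 1)[0] == pytest.approx(2.0)

    def test_pair_l2_is_half_mean_abs_difference(self):
        # enumerate ordered pairs of (0, 1): L2 = E(X_(2:2)-X_(1:2))/2 = 0.5
        assert sample_lmoments_ustat([0.0, 1.0], 2)[1] == pytest.approx(0.5)

    def test_degenerate_sample(self):
        L = sample_lmoments_ustat([0.0, 0.0, 0.0, 0.0], 4)
        assert np.allclose(L[1:], 0.0)

    def test_needs_enough_observations(self):
        with pytest.raises(ValueError):
            sample_lmoments_ustat([1.0, 2.0], 3)

    def test_gini_half_mean_abs_difference(self, rng):
        x = rng.lognormal(0, 0.8, 200)
        gini_mad = np.abs(x[:, None] - x[None, :]).sum() / (200 * 199)
        assert sample_lmoments_ustat(x, 2)[1] == pytest.approx(gini_mad / 2)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.1, 10), st.floats(-5, 5), st.integers(0, 100))
    def test_location_scale_equivariance(self, a, b, seed):
        x = np.random.default_rng(seed).lognormal(0, 1, 50)
        L = sample_lmoments_ustat(x, 4)
        La = sample_lmoments_ustat(a * x + b, 4)
        assert La[0] == pytest.approx(a * L[0] + b, rel=1e-9, abs=1e-9)
        assert np.allclose(La[1:], a * L[1:], rtol=1e-9, atol=1e-9)

    def test_l2_nonnegative(self, rng):
        for _ in range(5):
            x = rng.normal(size=30)
            assert sample_lmoments_ustat(x, 2)[1] >= 0


class TestLMomentsFromQuantile:
    def test_uniform_closed_form(self):
        p = np.linspace(0.0005, 0.9995, 2001)
        L = lmoments_from_quantile((p, p), 4)
        assert np.allclose(L, [0.5, 1 / 6, 0.0, 0.0], atol=1e-6)

    def test_exponential_closed_form(self):
        p = np.linspace(1e-6, 1 - 1e-6, 200001)
        L = lmoments_from_quantile((p, -np.log1p(-p)), 4)
        assert np.allclose(L, [1.0, 0.5, 1 / 6, 1 / 12], atol=2e-4)

    def test_constant(self):
        # exact up to the trapezoid quadrature error of the default grid
        p = default_p_grid()
        L = lmoments_from_quantile((p, np.full_like(p, 3.0)), 4)
        assert L[0] == pytest.approx(3.0, abs=1e-10)
        assert np.allclose(L[1:], 0.0, atol=2e-3)


class TestReconstruction:
    def test_constant_series(self):
        qf = reconstruct_quantile_from_lmoments([2.5, 0, 0, 0], 1)
        assert np.allclose(qf.values, 2.5)

    def test_uniform_series_recovers_identity(self):
        qf = reconstruct_quantile_from_lmoments([0.5, 1 / 6, 0, 0], 2)
        assert np.allclose(qf.values, qf.p_grid, atol=1e-12)

    def test_projection_roundtrip(self):
        # orthogonality: projecting the K-term series returns the L-moments
        p = np.linspace(0.0005, 0.9995, 4001)
        L_in = np.array([1.0, 0.4, -0.05, 0.02])
        qf = reconstruct_quantile_from_lmoments(L_in, 4, p_grid=p)
        L_out = lmoments_from_quantile(qf, 4)
        assert np.allclose(L_out, L_in, atol=1e-6)

    def test_too_many_orders_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_quantile_from_lmoments([1.0], 2)


class TestTimeVaryingLMoments:
    def test_constant_panel(self, constant_panel):
        lm = time_varying_lmoments(constant_panel)
        assert np.allclose(lm.order(1), 7.5)
        assert np.allclose(lm.values[1:], 0.0)

    def test_order1_equals_epoch_aggregation(self, rng):
        panel = make_panel(rng.gamma(1, 10, (2, MINUTES_PER_DAY)))
        lm = time_varying_lmoments(panel)
        _, curve = aggregate_to_epochs(panel, 10)
        assert np.allclose(lm.order(1), curve)

    def test_agrees_with_td_projection(self, rng):
        # dual-estimator check on windowed pooled samples
        panel = make_panel(rng.lognormal(2, 0.7, (5, MINUTES_PER_DAY)))
        lm = time_varying_lmoments(panel)
        td = build_td_object(panel)
        proj = np.vstack([
            lmoments_from_quantile((td.p_grid, td.Q[i]), 4)
            for i in range(td.t_grid.size)]).T
        # pooled windows hold ~50 values; the two estimators agree up to
        # the O(1/n_pool) boundary discrepancy of the interpolation grid
        scale = np.abs(lm.values[1]).mean()
        assert np.max(np.abs(lm.values - proj)) < 0.25 * scale + 0.05

    def test_small_window_higher_orders_missing(self):
        vals = np.full((1, MINUTES_PER_DAY), np.nan)
        vals[0, :2] = [1.0, 2.0]   # first epoch pools only 2 values
        lm = time_varying_lmoments(make_panel(np.where(np.isnan(vals), np.nan, vals)))
        assert np.isfinite(lm.values[:2, 0]).all()
        assert np.isnan(lm.values[2:, 0]).all()


class TestMeanConservation:
    def test_quantile_integral_refines_to_sample_mean(self, rng):
        x = rng.lognormal(0, 0.6, 2000)
        errs = []
        for m in (99, 399, 1599):
            p = np.arange(1, m + 1) / (m + 1)
            qf = estimate_quantile_function(x, p)
            errs.append(abs(quantile_integral_mean(qf) - x.mean()))
        assert errs[-1] < errs[0]
        assert errs[-1] / x.mean() < 5e-3

    def test_td_mean_recovers_panel_mean(self, rng):
        panel = make_panel(rng.lognormal(2, 0.8, (7, MINUTES_PER_DAY))
                           * (rng.random((7, MINUTES_PER_DAY)) < 0.5))
        td = build_td_object(panel)
        xbar = panel.overall_mean()
        assert abs(td_overall_mean(td) - xbar) / xbar < 0.01
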