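"""FPCA, group-exponential-lasso selection, and the L-moment SOFR refit."""

import numpy as np
import pytest

from sotdr.bases import trapezoid_weights, BSplineBasis, eval_shifted_legendre
from sotdr.distributional import default_p_grid
from sotdr.sofr import FittedSOFR, functional_design
from sotdr.sotdr_l import (
    assemble_beta_star,
    fit_gel_selection,
    fpca,
    refit_selected_sofr,
)
from sotdr.synthetic import simulate_lmoment_curve_study

from conftest import make_study

T_GRID = (np.arange(144) * 10 + 5.5) / 60.0


class TestFPCA:
    def test_identical_curves_degenerate(self):
        curves = np.tile(np.sin(T_GRID), (10, 1))
        dec = fpca(curves, T_GRID)
        assert dec.n_retained == 0
        assert dec.scores.shape == (10, 0)

    def test_rank_one_recovery(self, rng):
        psi = np.sin(2 * np.pi * T_GRID / 24)
        a = rng.normal(0, 2, 60)
        curves = 1.0 + np.outer(a, psi)
        dec = fpca(curves, T_GRID)
        assert dec.n_retained == 1
        w = trapezoid_weights(T_GRID)
        psi_n = psi / np.sqrt(w @ psi ** 2)
        cos = abs(dec.eigenfunctions[:, 0] @ (w * psi_n))
        assert cos >= 0.999
        r = np.corrcoef(dec.scores[:, 0], a)[0, 1]
        assert abs(r) >= 0.999

    def test_eigenfunctions_orthonormal_and_eigenvalues_sum(self, rng):
        curves = rng.normal(size=(40, T_GRID.size))
        dec = fpca(curves, T_GRID, pve=0.999)
        w = trapezoid_weights(T_GRID)
        G = dec.eigenfunctions.T @ (w[:, None] * dec.eigenfunctions)
        assert np.allclose(G, np.eye(dec.n_retained), atol=1e-8)
        centered = curves - curves.mean(0)
        total = np.sum((centered ** 2) @ w) / (curves.shape[0] - 1)
        assert dec.total_variance == pytest.approx(total, abs=1e-8)

    def test_reconstruction_error_bounded_by_pve(self, rng):
        modes = np.column_stack([np.sin(2 * np.pi * T_GRID / 24),
                                 np.cos(2 * np.pi * T_GRID / 24),
                                 np.sin(4 * np.pi * T_GRID / 24),
                                 np.cos(4 * np.pi * T_GRID / 24)])
        curves = rng.normal(size=(80, 4)) * [2, 1, 0.5, 0.25] @ modes.T
        dec = fpca(curves, T_GRID, pve=0.9)
        recon = dec.reconstruct()
        w = trapezoid_weights(T_GRID)
        centered = curves - curves.mean(0)
        rel = np.sum(((curves - recon) ** 2) @ w) / np.sum((centered ** 2) @ w)
        assert rel <= (1 - dec.pve) + 1e-8

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            fpca(np.zeros((2, T_GRID.size)), T_GRID)


class TestGELSelection:
    def test_pure_noise_moderate_lambda_selects_nothing(self):
        curves, _, _ = simulate_lmoment_curve_study(n=200, seed=3)
        r = np.random.default_rng(1)
        study = make_study(r.normal(size=200))
        decs = {k: fpca(curves[k], T_GRID) for k in curves}
        from sotdr._solvers import lambda_max
        S = np.column_stack([decs[k].scores for k in sorted(decs)])
        S = S / S.std(axis=0)
        X = np.column_stack([np.ones(study.n), S])
        pf = np.concatenate([[0.0], np.ones(S.shape[1])])
        lmax = lambda_max(X, study.y, "gaussian", pf)
        sel = fit_gel_selection(study, decs, lam=1.001 * lmax)
        assert sel.selected_orders == []

    def test_path_endpoints(self):
        # empty selection at lambda_max, every group active at lambda = 0
        curves, study, _ = simulate_lmoment_curve_study(n=250, snr=2.0,
                                                        seed=12)
        decs = {k: fpca(curves[k], T_GRID) for k in curves}
        from sotdr._solvers import lambda_max
        S = np.column_stack([decs[k].scores for k in sorted(decs)])
        S = S / S.std(axis=0)
        X = np.column_stack([np.ones(study.n), S])
        pf = np.concatenate([[0.0], np.ones(S.shape[1])])
        lmax = lambda_max(X, study.y, "gaussian", pf)
        empty = fit_gel_selection(study, decs, lam=1.001 * lmax)
        assert empty.selected_orders == []
        full = fit_gel_selection(study, decs, lam=0.0)
        assert full.selected_orders == [1, 2, 3, 4]

    def test_order3_signal_selected(self):
        hits = 0
        for s in range(10):
            curves, study, _ = simulate_lmoment_curve_study(
                n=300, snr=3.0, seed=50 + s)
            decs = {k: fpca(curves[k], T_GRID) for k in curves}
            sel = fit_gel_selection(study, decs, cv_seed=s)
            hits += 3 in sel.selected_orders
        assert hits >= 8

    def test_zero_lambda_matches_glm_oracle(self):
        import statsmodels.api as sm
        curves, study, _ = simulate_lmoment_curve_study(n=300, seed=9)
        decs = {k: fpca(curves[k], T_GRID) for k in curves}
        sel = fit_gel_selection(study, decs, lam=0.0)
        S = np.column_stack([decs[r].scores for r in sorted(decs)])
        X = np.column_stack([np.ones(study.n), S])
        oracle = sm.GLM(study.y, X).fit()
        coefs = np.concatenate([sel.group_coefs[r] for r in sorted(decs)])
        assert np.max(np.abs(coefs - oracle.params[1:])) < 1e-6
        assert sel.alpha == pytest.approx(oracle.params[0], abs=1e-6)

    def test_grouplasso_fallback_runs(self):
        curves, study, _ = simulate_lmoment_curve_study(n=200, snr=3.0, seed=4)
        decs = {k: fpca(curves[k], T_GRID) for k in curves}
        sel = fit_gel_selection(study, decs, penalty="grouplasso", cv_seed=0)
        assert sel.penalty == "grouplasso"
        assert 3 in sel.selected_orders


class TestAssembleBetaStar:
    def test_zero_coefficients_zero_curves(self):
        curves, study, _ = simulate_lmoment_curve_study(n=100, seed=5)
        decs = {k: fpca(curves[k], T_GRID) for k in curves}
        sel = fit_gel_selection(study, decs, lam=1e3)
        bstar = assemble_beta_star(sel)
        assert all(np.all(v == 0) for v in bstar.values())

    def test_unit_coefficient_returns_eigenfunction(self):
        curves, study, _ = simulate_lmoment_curve_study(n=100, seed=6)
        decs = {k: fpca(curves[k], T_GRID) for k in curves}
        sel = fit_gel_selection(study, decs, lam=1e3)
        sel.group_coefs[3] = np.eye(decs[3].n_retained)[0]
        bstar = assemble_beta_star(sel)
        assert np.allclose(bstar[3], decs[3].eigenfunctions[:, 0])

    def test_matrix_product_oracle(self):
        curves, study, _ = simulate_lmoment_curve_study(n=100, seed=7)
        decs = {k: fpca(curves[k], T_GRID) for k in curves}
        sel = fit_gel_selection(study, decs, lam=1e3)
        c = np.array([0.5, -1.0, 0.25])[: decs[2].n_retained]
        sel.group_coefs[2] = c
        bstar = assemble_beta_star(sel)
        assert np.allclose(bstar[2], decs[2].eigenfunctions @ c)


class TestRefit:
    def test_single_order_delegates_to_sofr(self):
        curves, study, _ = simulate_lmoment_curve_study(n=150, snr=3.0, seed=8)
        refit = refit_selected_sofr(study, {3: curves[3]}, T_GRID)
        assert isinstance(refit, FittedSOFR)
        direct_design = functional_design(
            curves[3], T_GRID, study.Z,
            BSplineBasis((T_GRID[0], T_GRID[-1]), 12))
        assert np.array_equal(refit.design.J, direct_design.J)

    def test_order1_only_reproduces_diurnal_sofr_design(self):
        # offering only the first L-moment curves is exactly SOFR on the
        # diurnal mean curves: identical functional design matrix
        curves, study, _ = simulate_lmoment_curve_study(n=100, seed=2)
        refit = refit_selected_sofr(study, {1: curves[1]}, T_GRID)
        basis = BSplineBasis((T_GRID[0], T_GRID[-1]), 12)
        expected = functional_design(curves[1], T_GRID, study.Z, basis)
        assert np.array_equal(refit.design.J, expected.J)

    def test_positive_bump_effect_recovered(self):
        signs = []
        for s in range(6):
            curves, study, beta_true = simulate_lmoment_curve_study(
                n=300, snr=3.0, seed=200 + s)
            refit = refit_selected_sofr(study, {3: curves[3]}, T_GRID)
            bh = refit.beta_hat()
            core = beta_true > 0.7 * beta_true.max()
            signs.append(np.mean(bh[core] > 0))
        assert np.median(signs) == 1.0

    def test_multiple_orders_additive(self):
        curves, study, _ = simulate_lmoment_curve_study(n=150, snr=3.0, seed=3)
        refit = refit_selected_sofr(study, {1: curves[1], 3: curves[3]},
                                    T_GRID)
        assert sorted(refit.beta_curves) == [1, 3]
        assert all(v.size == T_GRID.size for v in refit.beta_curves.values())

    def test_zero_orders_covariates_only(self):
        curves, study, _ = simulate_lmoment_curve_study(n=100, seed=4)
        res = refit_selected_sofr(study, {}, T_GRID)
        assert res.params.size == 1   # intercept only (no covariates here)


class TestSOTDRLEquivalence:
    def test_lmoment_linear_predictor_matches_tensor_form(self):
        # With Legendre polynomials as the p-basis, the additive L-moment
        # linear predictor equals the bivariate TD form for the same theta:
        # sum_l int L_il(t) beta*_l(t) dt = int int Q_i(t,p) beta(t,p) dt dp
        import sys
        sys.path.insert(0, str(__import__("pathlib").Path(__file__).parent))
        from test_sotdr import random_tds

        tds = random_tds(8, seed=21)
        p_grid = default_p_grid()
        K0, L0 = 6, 4
        basis_t = BSplineBasis((0.0, 24.0), K0)
        r = np.random.default_rng(0)
        theta = r.normal(size=(K0, L0))
        t = tds[0].t_hours
        BT = basis_t.evaluate(t)
        P = np.column_stack([eval_shifted_legendre(l, p_grid)
                             for l in range(L0)])
        wt = trapezoid_weights(t)
        wp = trapezoid_weights(p_grid)
        for td in tds:
            # bivariate route
            surf = BT @ theta @ P.T
            lp_biv = float(np.sum(wt[:, None] * td.Q * surf * wp[None, :]))
            # L-moment route: L_il(t) from the same TD rows
            L = np.vstack([
                np.trapezoid(td.Q * P[:, l][None, :], p_grid, axis=1)
                for l in range(L0)])
            beta_star = (BT @ theta).T            # (L0, n_t)
            lp_lm = float(np.sum((L * beta_star) @ wt))
            assert lp_lm == pytest.approx(lp_biv, rel=5e-3)
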