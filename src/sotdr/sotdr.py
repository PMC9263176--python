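"""Scalar-on-time-by-distribution regression (SOTDR).

The model links a scalar outcome to the subject's bivariate
time-by-distribution object ``Q_i(t, p)`` through

    g(mu_i) = alpha + Z_i' gamma + \\int_0^1 \\int_T Q_i(t,p) beta(t,p) dt dp,

with the coefficient surface expanded in a tensor product of cubic
B-splines, ``beta(t,p) = sum_{k,l} theta_{k,l} B_{T,k}(t) B_{P,l}(p)``
(``K_0 = L_0 = 12`` by default).  Under the expansion the model is a GLM
in the stacked tensor features
``W_i^{k,l} = \\int\\int Q_i(t,p) B_{T,k}(t) B_{P,l}(p) dt dp``.

Estimation is two-step:

1. minimize the penalized criterion ``-2 log L + lambda ||theta||_1``
   (intercept and covariates unpenalized), with lambda chosen by 5-fold
   cross-validated deviance over a log-spaced path — this selects the
   active tensor cells S;
2. refit an unpenalized GLM on the covariates plus the selected features,
   which also removes the LASSO shrinkage bias and provides the
   likelihood-ratio test of inclusion (2 (logL_full - logL_reduced)
   against chi-square with |S| degrees of freedom).

The fitted surface is assembled from the step-2 coefficients with zeros
in the unselected cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from ._solvers import cv_lasso_glm, lasso_glm
from .actigraphy_io import StudyTable, load_artifact, save_artifact
from .bases import BSplineBasis, trapezoid_weights
from .distributional import TDObject
from .sofr import _sm_family

logger = logging.getLogger("sotdr")

__all__ = [
    "TensorFeatureMatrix",
    "FittedSOTDR",
    "impute_td",
    "tensor_features",
    "fit_sotdr",
    "assemble_beta_surface",
    "lrt_inclusion",
    "predict_sotdr",
]


@dataclass
class TensorFeatureMatrix:
    """Subject x (K0*L0) matrix of tensor-product quadrature features.

    Columns are ordered row-major in (k, l): column ``k * L0 + l`` holds
    ``W^{k+1, l+1}``.
    """

    W: np.ndarray
    basis_t: BSplineBasis
    basis_p: BSplineBasis
    t_grid: np.ndarray   # hours
    p_grid: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    @property
    def K0(self) -> int:
        return self.basis_t.n_basis

    @property
    def L0(self) -> int:
        return self.basis_p.n_basis

    def column_index(self, k: int, l: int) -> int:
        """Column of the (k, l) cell, 1-based in both arguments."""
        return (k - 1) * self.L0 + (l - 1)


def impute_td(td: TDObject) -> TDObject:
    """Fill missing TD epochs by linear interpolation along t at fixed p."""
    Q = td.Q.copy()
    bad = np.isnan(Q).any(axis=1)
    if bad.any():
        good = ~bad
        if not good.any():
            raise ValueError("cannot impute an all-missing TD object")
        for j in range(Q.shape[1]):
            Q[bad, j] = np.interp(td.t_grid[bad], td.t_grid[good],
                                  Q[good, j])
        logger.info("imputed %d missing epochs for subject %s",
                    int(bad.sum()), td.subject_id)
    return TDObject(td.subject_id, td.t_grid, td.p_grid, Q, td.h,
                    td.pooled_sizes)


def tensor_features(
    td_objects: list[TDObject],
    K0: int = 12,
    L0: int = 12,
    t_domain: tuple[float, float] = (0.0, 24.0),
) -> TensorFeatureMatrix:
    """Two-dimensional trapezoid quadrature of each TD object against the
    tensor basis products."""
    if not td_objects:
        raise ValueError("no TD objects given")
    t_hours = td_objects[0].t_hours
    p_grid = td_objects[0].p_grid
    for td in td_objects[1:]:
        if (td.t_hours.shape != t_hours.shape
                or td.p_grid.shape != p_grid.shape
                or not np.allclose(td.t_hours, t_hours)
                or not np.allclose(td.p_grid, p_grid)):
            raise ValueError("all TD objects must share the same grids")
    basis_t = BSplineBasis(t_domain, K0)
    basis_p = BSplineBasis((0.0, 1.0), L0)
    WT = trapezoid_weights(t_hours)[:, None] * basis_t.evaluate(t_hours)
    WP = trapezoid_weights(p_grid)[:, None] * basis_p.evaluate(p_grid)
    rows = []
    for td in td_objects:
        if np.isnan(td.Q).any():
            raise ValueError(
                f"subject {td.subject_id}: TD object has missing epochs; "
                "run impute_td() first"
            )
        rows.append((WT.T @ td.Q @ WP).ravel())
    return TensorFeatureMatrix(
        np.vstack(rows), basis_t, basis_p, t_hours, p_grid,
        [td.subject_id for td in td_objects],
    )


@dataclass
class FittedSOTDR:
    """Two-step SOTDR fit: selected cells, refit coefficients, LRT."""

    features: TensorFeatureMatrix
    selected: np.ndarray          # column indices in W
    alpha: float
    gamma: np.ndarray
    theta: np.ndarray             # length K0*L0, zeros off the selection
    cov_step2: np.ndarray         # covariance of [alpha, gamma, theta_S]
    lam: float
    family: str
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    llf_full: float
    llf_reduced: float
    covariate_names: list[str] = field(default_factory=list)
    step1_theta: np.ndarray | None = None

    @property
    def theta_matrix(self) -> np.ndarray:
        return self.theta.reshape(self.features.K0, self.features.L0)

    def save(self, path) -> None:
        save_artifact(
            {
                "kind": "sotdr",
                "basis_t": self.features.basis_t.to_dict(),
                "basis_p": self.features.basis_p.to_dict(),
                "t_grid": self.features.t_grid,
                "p_grid": self.features.p_grid,
                "selected": self.selected,
                "alpha": self.alpha,
                "gamma": self.gamma,
                "theta": self.theta,
                "cov_step2": self.cov_step2,
                "lam": self.lam,
                "family": self.family,
                "lrt": [self.lrt_stat, self.lrt_df, self.lrt_p],
                "llf": [self.llf_full, self.llf_reduced],
                "covariate_names": self.covariate_names,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "FittedSOTDR":
        d = load_artifact(path, expected_kind="sotdr")
        feats = TensorFeatureMatrix(
            W=np.empty((0, 0)),
            basis_t=BSplineBasis.from_dict(d["basis_t"]),
            basis_p=BSplineBasis.from_dict(d["basis_p"]),
            t_grid=np.asarray(d["t_grid"], float),
            p_grid=np.asarray(d["p_grid"], float),
        )
        stat, df, p = d["lrt"]
        llf_full, llf_red = d["llf"]
        return cls(
            features=feats,
            selected=np.asarray(d["selected"], int),
            alpha=float(d["alpha"]),
            gamma=np.asarray(d["gamma"], float),
            theta=np.asarray(d["theta"], float),
            cov_step2=np.asarray(d["cov_step2"], float),
            lam=float(d["lam"]),
            family=d["family"],
            lrt_stat=float(stat), lrt_df=int(df), lrt_p=float(p),
            llf_full=float(llf_full), llf_reduced=float(llf_red),
            covariate_names=list(d["covariate_names"]),
        )


def fit_sotdr(
    study: StudyTable,
    features: TensorFeatureMatrix,
    lam: float | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    cv_folds: int = 5,
    cv_seed: int = 0,
    selected: np.ndarray | None = None,
) -> FittedSOTDR:
    """Two-step LASSO-then-refit estimation of the SOTDR model.

    Step-1 columns are standardized to unit variance before the L1
    penalty (and destandardized for reporting); constant columns are
    dropped from the penalized block with a warning.  ``lam=None``
    triggers 5-fold cross-validated deviance selection over a log-spaced
    path from ``lambda_max`` down to ``lambda_min_ratio * lambda_max``
    with ties broken toward the sparsest model; ``lam=numpy.inf`` forces
    the covariates-only model.  A precomputed ``selected`` column set
    (e.g. from an independent split) skips step 1 entirely.
    """
    W = np.asarray(features.W, float)
    n, m = W.shape
    if n != study.n:
        raise ValueError("feature rows do not match study table")
    q = study.Z.shape[1]

    sd = W.std(axis=0)
    usable = sd > 0
    if not usable.all():
        logger.warning("dropping %d constant tensor columns from step 1",
                       int((~usable).sum()))
    Ws = np.zeros_like(W)
    Ws[:, usable] = W[:, usable] / sd[usable]

    X = np.column_stack([np.ones(n), study.Z, Ws[:, usable]])
    pf = np.concatenate([np.zeros(1 + q), np.ones(int(usable.sum()))])

    given_selected = selected is not None
    if given_selected:
        selected = np.asarray(selected, int)
        lam_used = float("nan")
    elif lam is not None and np.isinf(lam):
        selected = np.array([], dtype=int)
        lam_used = float("inf")
    else:
        if lam is None:
            cv = cv_lasso_glm(X, study.y, study.family, pf,
                              n_lambda=n_lambda,
                              lambda_min_ratio=lambda_min_ratio,
                              folds=cv_folds, seed=cv_seed)
            lam_used = cv["lambda_best"]
            coef = cv["coef_best"]
        else:
            lam_used = float(lam)
            coef = lasso_glm(X, study.y, study.family, lam_used, pf)
        theta_std = coef[1 + q:]
        sel_local = np.flatnonzero(theta_std != 0)
        cols = np.flatnonzero(usable)
        selected = cols[sel_local]
        # cap the selection so step 2 stays identifiable
        cap = min(m, n - q - 1)
        if selected.size > cap:
            order = np.argsort(-np.abs(theta_std[sel_local]))
            selected = np.sort(selected[order[:cap]])
            logger.warning("selection truncated to %d columns", cap)

    step1_theta = None
    if not given_selected and lam is not None and not np.isinf(lam):
        # destandardized step-1 estimates (useful for the lam=0 oracle)
        step1_theta = np.zeros(m)
        step1_theta[np.flatnonzero(usable)] = coef[1 + q:] / sd[usable]

    # ---- step 2: unpenalized refit on (Z, W_S) ------------------------
    X_red = np.column_stack([np.ones(n), study.Z])
    fam = _sm_family(study.family)
    res_red = sm.GLM(study.y, X_red, family=fam).fit()
    if selected.size:
        X_full = np.column_stack([X_red, W[:, selected]])
        res_full = sm.GLM(study.y, X_full, family=fam).fit()
        theta = np.zeros(m)
        theta[selected] = res_full.params[1 + q:]
        llf_full = float(res_full.llf)
        cov2 = np.asarray(res_full.cov_params())
        alpha = float(res_full.params[0])
        gamma = np.asarray(res_full.params[1:1 + q])
    else:
        theta = np.zeros(m)
        llf_full = float(res_red.llf)
        cov2 = np.asarray(res_red.cov_params())
        alpha = float(res_red.params[0])
        gamma = np.asarray(res_red.params[1:1 + q])

    llf_red = float(res_red.llf)
    stat = 2.0 * (llf_full - llf_red)
    if stat < -1e-6 * (abs(llf_full) + 1):
        raise FloatingPointError(
            f"likelihood decreased on the larger model (LRT={stat:.3g})"
        )
    stat = max(stat, 0.0)
    df = int(selected.size)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0

    return FittedSOTDR(
        features=features, selected=np.asarray(selected, int),
        alpha=alpha, gamma=gamma, theta=theta, cov_step2=cov2,
        lam=float(lam_used), family=study.family,
        lrt_stat=float(stat), lrt_df=df, lrt_p=p,
        llf_full=llf_full, llf_reduced=llf_red,
        covariate_names=list(study.covariate_names),
        step1_theta=step1_theta,
    )


def assemble_beta_surface(fit: FittedSOTDR, t_grid=None, p_grid=None
                          ) -> np.ndarray:
    """Evaluate ``beta_hat(t, p)`` on a grid (default: the feature grids)."""
    t_grid = fit.features.t_grid if t_grid is None else np.asarray(t_grid, float)
    p_grid = fit.features.p_grid if p_grid is None else np.asarray(p_grid, float)
    BT = fit.features.basis_t.evaluate(t_grid)
    BP = fit.features.basis_p.evaluate(p_grid)
    return BT @ fit.theta_matrix @ BP.T


def lrt_inclusion(fit: FittedSOTDR):
    """Likelihood-ratio test of inclusion of the selected TD features.

    Returns ``(statistic, df, p_value)`` as computed in step 2.
    """
    return fit.lrt_stat, fit.lrt_df, fit.lrt_p


def predict_sotdr(fit: FittedSOTDR, td_objects=None, Z=None, W=None):
    """Response-scale predictions for new subjects.

    Either raw TD objects (converted through :func:`tensor_features` on
    the fitted bases/grids) or a precomputed feature matrix ``W``.
    """
    if W is None:
        if td_objects is None:
            raise ValueError("give td_objects or W")
        t0 = td_objects[0]
        if not (np.allclose(t0.t_hours, fit.features.t_grid)
                and np.allclose(t0.p_grid, fit.features.p_grid)):
            raise ValueError("TD grids do not match the fitted model")
        feats = tensor_features(td_objects, fit.features.K0, fit.features.L0,
                                fit.features.basis_t.domain)
        W = feats.W
    W = np.asarray(W, float)
    if Z is None:
        Z = np.empty((W.shape[0], 0))
    Z = np.atleast_2d(np.asarray(Z, float))
    eta = fit.alpha + Z @ fit.gamma + W @ fit.theta
    return eta if fit.family == "gaussian" else expit(eta)
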