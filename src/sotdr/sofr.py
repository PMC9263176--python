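"""Penalized scalar-on-function regression (SOFR).

Fits the three comparator models for a scalar outcome ``Y_i`` from an
exponential family with link ``g``:

* GLM on the scalar activity average:
  ``g(mu_i) = alpha + Z_i' gamma + Xbar_i beta``;
* SOFR on diurnal curves: ``g(mu_i) = alpha + Z_i' gamma +
  \\int_T X_i(t) beta(t) dt`` with ``T = (0, 24)`` hours;
* SOFR on quantile functions: the same with ``\\int_0^1 Q_i(p) beta(p) dp``.

The coefficient function is expanded in ``K`` cubic B-splines (default 12)
with an order-2 difference penalty; the smoothing parameter is chosen by a
restricted-likelihood criterion (Gaussian REML; binomial via the working
model at PQL convergence) over a log-spaced grid refined by golden-section
search.  Significance of the functional term is assessed by a Wald-type
quadratic form of the spline coefficient block against its posterior
covariance with rank equal to the rounded effective degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .actigraphy_io import StudyTable, load_artifact, save_artifact
from .bases import BSplineBasis, difference_penalty, trapezoid_weights

logger = logging.getLogger("sotdr")

__all__ = [
    "FunctionalDesign",
    "FittedSOFR",
    "functional_design",
    "fit_scalar_glm",
    "fit_penalized_sofr",
    "global_coefficient_test",
    "predict_sofr",
]


@dataclass
class FunctionalDesign:
    """Subject x basis matrix of ``\\int X_i(u) B_k(u) du`` terms."""

    J: np.ndarray          # (n, K) integral terms
    Z: np.ndarray          # (n, q) covariates
    basis: BSplineBasis
    grid: np.ndarray
    weights: np.ndarray    # trapezoid quadrature weights on grid

    @property
    def X(self) -> np.ndarray:
        """Full design [1 | Z | J]."""
        n = self.J.shape[0]
        return np.column_stack([np.ones(n), self.Z, self.J])


def functional_design(curves: np.ndarray, grid, Z, basis: BSplineBasis
                      ) -> FunctionalDesign:
    """Trapezoid-quadrature functional design matrix.

    ``curves`` is (n_subjects, len(grid)); no missing values allowed.
    """
    curves = np.asarray(curves, float)
    grid = np.asarray(grid, float)
    if curves.ndim != 2 or curves.shape[1] != grid.size:
        raise ValueError("curves must be (n, len(grid))")
    if np.isnan(curves).any():
        raise ValueError("curves contain missing values; impute upstream")
    w = trapezoid_weights(grid)
    B = basis.evaluate(grid)
    J = curves @ (w[:, None] * B)
    Z = np.atleast_2d(np.asarray(Z, float))
    if Z.size == 0:
        Z = np.empty((curves.shape[0], 0))
    return FunctionalDesign(J, Z, basis, grid, w)


# ---------------------------------------------------------------------------
# Model (1): GLM on scalar averages
# ---------------------------------------------------------------------------


@dataclass
class FittedScalarGLM:
    """GLM fit of the outcome on covariates + scalar activity average."""

    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    names: list[str]
    family: str
    llf: float
    deviance: float
    result: object = field(repr=False, default=None)

    @property
    def beta_activity(self) -> float:
        return float(self.params[-1])

    def predict(self, Z, xbar):
        Z = np.atleast_2d(np.asarray(Z, float))
        xbar = np.asarray(xbar, float)
        X = np.column_stack([np.ones(xbar.size), Z, xbar])
        eta = X @ self.params
        return eta if self.family == "gaussian" else expit(eta)


def _sm_family(family: str):
    if family == "gaussian":
        return sm.families.Gaussian()
    if family == "binomial":
        return sm.families.Binomial()
    raise ValueError(f"unknown family {family!r}")


def fit_scalar_glm(study: StudyTable, xbar) -> FittedScalarGLM:
    """Maximum-likelihood GLM ``g(mu) = alpha + Z'gamma + Xbar beta``."""
    xbar = np.asarray(xbar, float)
    if xbar.size != study.n:
        raise ValueError("xbar must have one value per subject")
    if np.ptp(xbar) == 0:
        raise ValueError(
            "scalar average is constant across subjects: the activity "
            "effect is collinear with the intercept and unidentifiable"
        )
    X = np.column_stack([np.ones(study.n), study.Z, xbar])
    names = ["intercept", *study.covariate_names, "xbar"]
    res = sm.GLM(study.y, X, family=_sm_family(study.family)).fit()
    if study.family == "binomial":
        mu = res.fittedvalues
        if np.all((mu < 1e-8) | (mu > 1 - 1e-8)):
            raise ValueError("perfect separation in logistic fit")
        if np.any(np.abs(res.params) > 1e3):
            logger.warning("possible separation: extreme logistic coefficients")
    return FittedScalarGLM(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        pvalues=np.asarray(res.pvalues),
        names=names,
        family=study.family,
        llf=float(res.llf),
        deviance=float(res.deviance),
        result=res,
    )


# ---------------------------------------------------------------------------
# penalized SOFR
# ---------------------------------------------------------------------------


def _penalized_irls(X, y, S, lam, family, tol=1e-8, max_iter=100):
    """Penalized IRLS; returns (beta, W diag, z, converged)."""
    n, p = X.shape
    if family == "gaussian":
        H = X.T @ X + lam * S
        beta = np.linalg.solve(H, X.T @ y)
        return beta, np.ones(n), y, True
    beta = np.zeros(p)
    beta[0] = np.log(np.clip(y.mean(), 1e-6, 1 - 1e-6) /
                     (1 - np.clip(y.mean(), 1e-6, 1 - 1e-6)))
    dev_old = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-6, None)
        z = eta + (y - mu) / w
        H = X.T @ (w[:, None] * X) + lam * S
        beta = np.linalg.solve(H, X.T @ (w * z))
        mu = expit(X @ beta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        dev = -2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            return beta, w, z, True
        dev_old = dev
    return beta, w, z, False


def _reml_score(X, y, S, lam, family, rank_S, null_dim):
    """Restricted-likelihood score (smaller is better)."""
    beta, w, z, _ = _penalized_irls(X, y, S, lam, family)
    H = X.T @ (w[:, None] * X) + lam * S
    sign, logdetH = np.linalg.slogdet(H)
    if sign <= 0:
        return np.inf, beta
    pen = lam * float(beta @ S @ beta)
    n = y.size
    if family == "gaussian":
        P = max(float(np.sum((y - X @ beta) ** 2)) + pen, 1e-300)
        score = (n - null_dim) * np.log(P) + logdetH - rank_S * np.log(lam)
    else:
        P = float(np.sum(w * (z - X @ beta) ** 2)) + pen
        score = P + logdetH - rank_S * np.log(lam)
    return score, beta


@dataclass
class FittedSOFR:
    """Penalized SOFR fit with assembled coefficient function."""

    design: FunctionalDesign
    coef: np.ndarray            # full coefficient vector [alpha, gamma, theta]
    cov: np.ndarray             # Bayesian posterior covariance, full
    lam: float
    edf: float                  # total effective degrees of freedom
    edf_spline: float
    family: str
    penalty_order: int
    phi: float                  # dispersion
    deviance: float
    llf: float
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_covariates(self) -> int:
        return self.design.Z.shape[1]

    @property
    def alpha(self) -> float:
        return float(self.coef[0])

    @property
    def gamma(self) -> np.ndarray:
        return self.coef[1:1 + self.n_covariates]

    @property
    def theta(self) -> np.ndarray:
        return self.coef[1 + self.n_covariates:]

    def beta_hat(self, grid=None) -> np.ndarray:
        """Assembled coefficient function on a grid (default: fit grid)."""
        grid = self.design.grid if grid is None else np.asarray(grid, float)
        return self.design.basis.evaluate(grid) @ self.theta

    def save(self, path) -> None:
        save_artifact(
            {
                "kind": "sofr",
                "basis": self.design.basis.to_dict(),
                "grid": self.design.grid,
                "coef": self.coef,
                "cov": self.cov,
                "lam": self.lam,
                "edf": self.edf,
                "edf_spline": self.edf_spline,
                "family": self.family,
                "penalty_order": self.penalty_order,
                "phi": self.phi,
                "deviance": self.deviance,
                "llf": self.llf,
                "covariate_names": self.covariate_names,
                "n_covariates": self.n_covariates,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "FittedSOFR":
        d = load_artifact(path, expected_kind="sofr")
        basis = BSplineBasis.from_dict(d["basis"])
        grid = np.asarray(d["grid"], float)
        q = int(d["n_covariates"])
        design = FunctionalDesign(
            J=np.empty((0, basis.n_basis)), Z=np.empty((0, q)),
            basis=basis, grid=grid, weights=trapezoid_weights(grid),
        )
        return cls(
            design=design,
            coef=np.asarray(d["coef"], float),
            cov=np.asarray(d["cov"], float),
            lam=float(d["lam"]),
            edf=float(d["edf"]),
            edf_spline=float(d["edf_spline"]),
            family=d["family"],
            penalty_order=int(d["penalty_order"]),
            phi=float(d["phi"]),
            deviance=float(d["deviance"]),
            llf=float(d["llf"]),
            covariate_names=list(d["covariate_names"]),
        )


def fit_penalized_sofr(
    study: StudyTable,
    curves,
    grid,
    n_basis: int = 12,
    penalty_order: int = 2,
    lam: float | None = None,
    domain: tuple[float, float] | None = None,
) -> FittedSOFR:
    """Fit a penalized SOFR model with automatic smoothing selection.

    Parameters
    ----------
    curves
        (n, len(grid)) functional predictor values.
    grid
        Argument grid (hours for diurnal curves, levels for quantile
        functions).
    lam
        Fixed smoothing parameter; if None (default) it is selected by
        the restricted-likelihood criterion.
    domain
        Basis domain; defaults to the grid range.
    """
    grid = np.asarray(grid, float)
    if domain is None:
        domain = (float(grid[0]), float(grid[-1]))
    basis = BSplineBasis(domain, n_basis)
    design = functional_design(curves, grid, study.Z, basis)
    X = design.X
    n, p = X.shape
    q = design.Z.shape[1]
    K = n_basis

    S = np.zeros((p, p))
    S[1 + q:, 1 + q:] = difference_penalty(K, penalty_order).matrix
    rank_S = K - penalty_order
    null_dim = 1 + q + penalty_order

    y = study.y
    family = study.family

    if lam is None:
        # scale-free grid centered on the trace ratio, then golden refine
        scale = np.trace(X.T @ X) / max(np.trace(S), 1e-12)
        grid_l = scale * np.geomspace(1e-6, 1e6, 25)
        scores = [ _reml_score(X, y, S, l, family, rank_S, null_dim)[0]
                   for l in grid_l ]
        i0 = int(np.nanargmin(scores))
        lo = grid_l[max(i0 - 1, 0)]
        hi = grid_l[min(i0 + 1, grid_l.size - 1)]
        gr = (np.sqrt(5) - 1) / 2
        a, b = np.log(lo), np.log(hi)
        c, d = b - gr * (b - a), a + gr * (b - a)
        fc = _reml_score(X, y, S, np.exp(c), family, rank_S, null_dim)[0]
        fd = _reml_score(X, y, S, np.exp(d), family, rank_S, null_dim)[0]
        for _ in range(30):
            if b - a < 1e-3:
                break
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - gr * (b - a)
                fc = _reml_score(X, y, S, np.exp(c), family, rank_S, null_dim)[0]
            else:
                a, c, fc = c, d, fd
                d = a + gr * (b - a)
                fd = _reml_score(X, y, S, np.exp(d), family, rank_S, null_dim)[0]
        lam = float(np.exp((a + b) / 2))

    beta, w, z, converged = _penalized_irls(X, y, S, lam, family)
    if not converged:
        logger.warning("penalized IRLS did not fully converge")
    XtWX = X.T @ (w[:, None] * X)
    H = XtWX + lam * S
    Hinv = np.linalg.inv(H)
    F = Hinv @ XtWX
    edf = float(np.trace(F))
    edf_spline = float(np.trace(F[1 + q:, 1 + q:]))

    eta = X @ beta
    if family == "gaussian":
        resid = y - eta
        dev = float(resid @ resid)
        phi = dev / max(n - edf, 1.0)
        llf = -0.5 * n * (np.log(2 * np.pi * dev / n) + 1.0)
    else:
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        dev = float(-2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        phi = 1.0
        llf = -dev / 2
    cov = Hinv * phi

    return FittedSOFR(
        design=design, coef=beta, cov=cov, lam=float(lam), edf=edf,
        edf_spline=edf_spline, family=family, penalty_order=penalty_order,
        phi=phi, deviance=dev, llf=llf,
        covariate_names=list(study.covariate_names),
    )


def global_coefficient_test(fit: FittedSOFR):
    """Wald-type global test of the functional coefficient.

    Quadratic form of the spline coefficient block against its posterior
    covariance, pseudo-inverted at rank = rounded spline EDF, referred to
    a chi-square distribution.  Returns ``(statistic, p_value)``.
    """
    q = fit.n_covariates
    theta = fit.theta
    if not np.any(theta):
        return 0.0, 1.0
    # work on the fitted-function scale: f = B theta on the grid
    B = fit.design.basis.evaluate(fit.design.grid)
    f = B @ theta
    V_theta = fit.cov[1 + q:, 1 + q:]
    V = B @ ((V_theta + V_theta.T) / 2) @ B.T
    evals, evecs = np.linalg.eigh(V)
    if evals.min() < -1e-8 * max(evals.max(), 1e-12):
        logger.warning("covariance not PSD; adding jitter")
        V = V + (1e-8 * max(evals.max(), 1e-8) - evals.min()) * np.eye(V.shape[0])
        evals, evecs = np.linalg.eigh(V)
    rank = int(np.clip(round(fit.edf_spline), 1, theta.size))
    idx = np.argsort(evals)[::-1][:rank]
    inv = evecs[:, idx] @ np.diag(1.0 / np.clip(evals[idx], 1e-12, None)) \
        @ evecs[:, idx].T
    stat = float(f @ inv @ f)
    if fit.family == "gaussian":
        # dispersion is estimated: F reference with the residual df
        rdf = max(fit.deviance / fit.phi, 1.0)
        p = float(stats.f.sf(stat / rank, rank, rdf))
    else:
        p = float(stats.chi2.sf(stat, df=rank))
    return stat, p


def predict_sofr(fit: FittedSOFR, curves, Z=None, grid=None):
    """Response-scale predictions for new curves.

    ``grid`` must match the training grid (default: assume it does).
    """
    curves = np.asarray(curves, float)
    if grid is not None:
        grid = np.asarray(grid, float)
        if grid.shape != fit.design.grid.shape or not np.allclose(
                grid, fit.design.grid):
            raise ValueError("prediction grid does not match training grid")
    if curves.shape[1] != fit.design.grid.size:
        raise ValueError("curve length does not match training grid")
    if Z is None:
        Z = np.empty((curves.shape[0], 0))
    Z = np.atleast_2d(np.asarray(Z, float))
    B = fit.design.basis.evaluate(fit.design.grid)
    J = curves @ (fit.design.weights[:, None] * B)
    eta = fit.alpha + Z @ fit.gamma + J @ fit.theta
    return eta if fit.family == "gaussian" else expit(eta)
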