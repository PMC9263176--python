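"""Model comparison: cross-validated AUC / R-squared and scalar biomarkers.

``repeated_cv`` runs repeated five-fold cross-validation (stratified by
class for binary outcomes) of any model exposing fit/predict callables
and reports the per-repeat, per-fold metric values.  For the
two-step time-by-distribution model the convention is to cross-validate
only the second (refit) stage: the tensor-feature columns selected once
in step 1 are held fixed across folds.  An honest nested option that
reruns the selection inside each training fold is available as a labeled
extension (``nested=True`` on the SOTDR model spec).

Scalar biomarkers contract each subject representation against its
fitted coefficient:

    bm_a  = Xbar_i * beta_hat                     (scalar average)
    bm_T  = \\int_T X_i(t) beta_hat(t) dt          (diurnal curve)
    bm_D  = \\int_0^1 Q_i(p) beta_hat(p) dp        (quantile function)
    bm_TD = \\int\\int Q_i(t,p) beta_hat(t,p) dt dp (time-by-distribution)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit

from ._solvers import _fold_ids
from .actigraphy_io import StudyTable
from .bases import trapezoid_weights
from .sofr import FittedSOFR, _sm_family
from .sotdr import FittedSOTDR, fit_sotdr

logger = logging.getLogger("sotdr")

__all__ = [
    "auc",
    "adjusted_r2",
    "CVReport",
    "repeated_cv",
    "cv_model_from_design",
    "sotdr_cv_model",
    "compute_biomarkers",
]


def auc(scores, labels) -> float:
    """Mann-Whitney concordance (ROC AUC) with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata
    r = rankdata(np.concatenate([neg, pos]))
    u = r[neg.size:].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def adjusted_r2(y, fitted, n_predictors: int) -> float:
    """1 - [RSS/(n-p-1)] / [TSS/(n-1)] — unbiased-variance-ratio R^2."""
    y = np.asarray(y, float)
    fitted = np.asarray(fitted, float)
    n = y.size
    p = int(n_predictors)
    if n <= p + 1:
        raise ValueError("need n > n_predictors + 1")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("outcome has zero variance; R^2 undefined")
    rss = float(np.sum((y - fitted) ** 2))
    return 1.0 - (rss / (n - p - 1)) / (tss / (n - 1))


@dataclass
class CVReport:
    """Repeated cross-validation results for one model."""

    metric: str
    values: np.ndarray         # (repeats, folds)
    folds: int
    repeats: int
    seed: int
    model: str = ""

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def per_repeat(self) -> np.ndarray:
        return np.nanmean(self.values, axis=1)

    def summary(self) -> dict:
        return {
            "metric": self.metric, "model": self.model,
            "mean": self.mean, "folds": self.folds,
            "repeats": self.repeats, "seed": self.seed,
            "repeat_sd": float(np.std(self.per_repeat, ddof=1))
            if self.repeats > 1 else 0.0,
        }


def repeated_cv(
    model,
    study: StudyTable,
    folds: int = 5,
    repeats: int = 10,
    metric: str = "auc",
    seed: int = 0,
) -> CVReport:
    """Repeated k-fold cross-validation of a fit/predict model spec.

    ``model`` is a mapping with callables ``fit(train_idx) -> state`` and
    ``predict(state, test_idx) -> scores`` plus an optional ``name``.
    Binary outcomes are stratified by class; fold membership is keyed by
    the seed, so identical data and seed give identical reports.  For the
    R^2 metric the out-of-fold predictions of each repeat are pooled and
    scored against the total sum of squares.
    """
    if metric not in ("auc", "r2"):
        raise ValueError("metric must be 'auc' or 'r2'")
    n = study.n
    if n < folds:
        raise ValueError("need at least one subject per fold")
    y = study.y
    values = np.full((repeats, folds), np.nan)
    r2_values = np.full(repeats, np.nan)
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        for attempt in range(10):
            ids = _fold_ids(n, y, folds, study.family, rng)
            ok = True
            if metric == "auc":
                for f in range(folds):
                    yf = y[ids == f]
                    if yf.size == 0 or yf.min() == yf.max():
                        ok = False
                if not ok:
                    logger.warning("degenerate fold; refolding with sub-seed")
                    rng = np.random.default_rng([seed, rep, 1 + attempt])
                    continue
            break
        pooled_pred = np.full(n, np.nan)
        for f in range(folds):
            tr = np.flatnonzero(ids != f)
            te = np.flatnonzero(ids == f)
            state = model["fit"](tr)
            pred = np.asarray(model["predict"](state, te), float)
            pooled_pred[te] = pred
            if metric == "auc":
                values[rep, f] = auc(pred, y[te])
        if metric == "r2":
            tss = float(np.sum((y - y.mean()) ** 2))
            rss = float(np.sum((y - pooled_pred) ** 2))
            r2_values[rep] = 1.0 - rss / tss
    if metric == "r2":
        values = r2_values[:, None]
        folds_out = 1
    else:
        folds_out = folds
    return CVReport(metric=metric, values=values, folds=folds if metric == "auc" else folds,
                    repeats=repeats, seed=seed,
                    model=str(model.get("name", "")))


def cv_model_from_design(X_features, study: StudyTable, name: str = "glm"):
    """Model spec refitting an unpenalized GLM on fixed feature columns.

    Used both for the scalar-average model and for the step-2-only
    cross-validation convention of the two-step TD model.
    """
    X_features = np.atleast_2d(np.asarray(X_features, float))
    if X_features.shape[0] != study.n:
        X_features = X_features.T
    fam = _sm_family(study.family)

    def fit(train_idx):
        X = np.column_stack([np.ones(len(train_idx)),
                             study.Z[train_idx], X_features[train_idx]])
        return sm.GLM(study.y[train_idx], X, family=fam).fit()

    def predict(state, test_idx):
        X = np.column_stack([np.ones(len(test_idx)),
                             study.Z[test_idx], X_features[test_idx]])
        eta = X @ np.asarray(state.params)
        return eta if study.family == "gaussian" else expit(eta)

    return {"fit": fit, "predict": predict, "name": name}


def sotdr_cv_model(fit: FittedSOTDR, study: StudyTable, W: np.ndarray,
                   nested: bool = False, **fit_kw):
    """Cross-validation spec for the two-step TD model.

    Default (``nested=False``): the step-1 selection from ``fit`` is held
    fixed and only the step-2 GLM is refit per fold.  ``nested=True`` is
    the labeled extension that reruns the full two-step estimator
    (selection included) inside every training fold.
    """
    W = np.asarray(W, float)
    if not nested:
        return cv_model_from_design(W[:, fit.selected] if fit.selected.size
                                    else np.empty((study.n, 0)),
                                    study, name="sotdr-step2cv")
    from .sotdr import TensorFeatureMatrix

    def fit_fn(train_idx):
        sub = StudyTable([study.subject_ids[i] for i in train_idx],
                         study.y[train_idx], study.Z[train_idx],
                         study.family, study.covariate_names)
        feats = TensorFeatureMatrix(W[train_idx], fit.features.basis_t,
                                    fit.features.basis_p,
                                    fit.features.t_grid, fit.features.p_grid)
        return fit_sotdr(sub, feats, **fit_kw)

    def predict_fn(state, test_idx):
        eta = state.alpha + study.Z[test_idx] @ state.gamma \
            + W[test_idx] @ state.theta
        return eta if study.family == "gaussian" else expit(eta)

    return {"fit": fit_fn, "predict": predict_fn, "name": "sotdr-nestedcv"}


# ---------------------------------------------------------------------------
# scalar biomarkers
# ---------------------------------------------------------------------------


def compute_biomarkers(
    xbar,
    diurnal_curves,
    t_grid_hours,
    quantile_curves,
    p_grid,
    td_objects,
    glm_fit,
    sofr_t_fit: FittedSOFR,
    sofr_q_fit: FittedSOFR,
    sotdr_fit: FittedSOTDR,
) -> dict:
    """The four scalar biomarkers from the four fitted models.

    Returns a dict with keys bm_a, bm_T, bm_D, bm_TD, each an array over
    subjects.
    """
    xbar = np.asarray(xbar, float)
    t_grid_hours = np.asarray(t_grid_hours, float)
    p_grid = np.asarray(p_grid, float)
    curves_t = np.asarray(diurnal_curves, float)
    curves_q = np.asarray(quantile_curves, float)
    if curves_t.shape[1] != t_grid_hours.size:
        raise ValueError("diurnal curve grid mismatch")
    if curves_q.shape[1] != p_grid.size:
        raise ValueError("quantile curve grid mismatch")
    if not np.allclose(sofr_t_fit.design.grid, t_grid_hours):
        raise ValueError("sofr-t fit grid does not match t_grid_hours")
    if not np.allclose(sofr_q_fit.design.grid, p_grid):
        raise ValueError("sofr-q fit grid does not match p_grid")

    bm_a = xbar * glm_fit.beta_activity
    wt = trapezoid_weights(t_grid_hours)
    bm_T = curves_t @ (wt * sofr_t_fit.beta_hat())
    wp = trapezoid_weights(p_grid)
    bm_D = curves_q @ (wp * sofr_q_fit.beta_hat())
    from .sotdr import assemble_beta_surface
    surf = assemble_beta_surface(sotdr_fit)
    t_td = sotdr_fit.features.t_grid
    p_td = sotdr_fit.features.p_grid
    kern = (trapezoid_weights(t_td)[:, None] * surf) \
        * trapezoid_weights(p_td)[None, :]
    bm_TD = np.array([float(np.sum(td.Q * kern)) for td in td_objects])
    return {"bm_a": bm_a, "bm_T": bm_T, "bm_D": bm_D, "bm_TD": bm_TD}
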