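"""Synthetic actigraphy panels and outcomes with the structure the models assume.

The generator emulates minute-level activity of a highly sedentary older
cohort: for group ``g`` and minute ``t``, activity is zero-inflated
lognormal,

    X(t) = Bernoulli(pi_g(t)) * LogNormal(m_g(t), s_g(t)),

so the marginal zero fraction at minute ``t`` is ``1 - pi_g(t)``.  Group 0
("control-like") has a bimodal diurnal activation/intensity profile with
morning and afternoon peaks; group 1 ("case-like") has a unimodal profile
with depressed intensity — hence depressed upper quantiles — during the
morning window.  Outcomes are generated forward from the
time-by-distribution model:

    g(mu_i) = alpha + Z_i' gamma + \\int\\int Q_i(t,p) beta(t,p) dt dp,

with a Gaussian error (identity link) or a Bernoulli draw (logit link).

Randomness is driven by one integer seed; each subject's panel uses the
sub-stream ``default_rng([seed, subject_index])`` so panels are
reproducible independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .actigraphy_io import MINUTES_PER_DAY, ActigraphyPanel, StudyTable
from .bases import trapezoid_weights
from .distributional import TDObject, build_td_object

__all__ = [
    "TrueBetaSurface",
    "make_true_beta_surface",
    "SyntheticScenario",
    "simulate_panel",
    "simulate_covariates",
    "simulate_outcomes",
    "simulate_study",
    "strong_signal_scenario",
    "null_scenario",
    "simulate_lmoment_curve_study",
]


# ---------------------------------------------------------------------------
# true coefficient surfaces
# ---------------------------------------------------------------------------


def _cos_bump(x, center, halfwidth):
    """Smooth compactly supported bump: cos^2 taper, zero outside support."""
    u = (np.asarray(x, float) - center) / halfwidth
    out = np.where(np.abs(u) < 1.0, np.cos(np.pi * u / 2.0) ** 2, 0.0)
    return out


@dataclass(frozen=True)
class TrueBetaSurface:
    """Ground-truth coefficient surface ``beta(t, p)`` for simulation.

    Kinds: ``constant`` (params: value), ``separable`` (params: t_center,
    t_halfwidth, p_center, p_halfwidth, amplitude — a product of two cos^2
    bumps), ``bump`` (same params; identical to separable, named for the
    localized-effect reading), ``two_bump`` (params: two bump parameter
    dicts with signed amplitudes).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("constant", "separable", "bump", "two_bump"):
            raise ValueError(f"unknown surface kind {self.kind!r}")

    def evaluate(self, t_hours, p) -> np.ndarray:
        t = np.asarray(t_hours, float)
        p = np.asarray(p, float)
        if self.kind == "constant":
            return np.full((t.size, p.size), float(self.params["value"]))
        if self.kind in ("separable", "bump"):
            q = self.params
            ft = _cos_bump(t, q["t_center"], q["t_halfwidth"])
            gp = _cos_bump(p, q["p_center"], q["p_halfwidth"])
            return q.get("amplitude", 1.0) * np.outer(ft, gp)
        # two_bump contrast
        out = np.zeros((t.size, p.size))
        for q in self.params["bumps"]:
            ft = _cos_bump(t, q["t_center"], q["t_halfwidth"])
            gp = _cos_bump(p, q["p_center"], q["p_halfwidth"])
            out += q.get("amplitude", 1.0) * np.outer(ft, gp)
        return out

    def support_mask(self, t_hours, p, threshold: float = 0.5) -> np.ndarray:
        """Grid cells where |beta| exceeds ``threshold`` * max |beta|."""
        surf = self.evaluate(t_hours, p)
        return np.abs(surf) >= threshold * np.abs(surf).max()


def make_true_beta_surface(kind: str, params: dict) -> TrueBetaSurface:
    return TrueBetaSurface(kind, dict(params))


# ---------------------------------------------------------------------------
# diurnal activity model
# ---------------------------------------------------------------------------


def _default_activation(group: int, t_hours: np.ndarray) -> np.ndarray:
    """Per-minute activation probability pi_g(t)."""
    base = 0.05 + 0.55 * _cos_bump(t_hours, 14.0, 9.0)      # awake envelope
    if group == 0:
        base = base + 0.20 * _cos_bump(t_hours, 9.0, 2.5) \
                    + 0.15 * _cos_bump(t_hours, 16.0, 2.5)
    else:
        base = base + 0.15 * _cos_bump(t_hours, 12.5, 4.0)
    return np.clip(base, 0.0, 0.95)


def _default_log_mean(group: int, t_hours: np.ndarray) -> np.ndarray:
    """Time-varying log-intensity m_g(t) of the nonzero activity."""
    m = np.log(60.0) + 1.2 * _cos_bump(t_hours, 13.5, 8.5)
    if group == 0:
        m = m + 0.9 * _cos_bump(t_hours, 9.0, 2.5) \
              + 0.6 * _cos_bump(t_hours, 16.0, 2.5)
    else:
        m = m + 0.4 * _cos_bump(t_hours, 12.5, 4.0)
    return m


def _default_log_sd(group: int, t_hours: np.ndarray) -> np.ndarray:
    return np.full_like(t_hours, 0.6)


@dataclass
class SyntheticScenario:
    """Generator parameters for one simulated study.

    Defaults describe the reference conditions used throughout the test
    suite: 400 subjects, 7 days of wear, half case-like subjects, a
    localized positive morning/upper-quantile effect, logit outcomes.
    """

    n_subjects: int = 400
    n_days: int = 7
    case_fraction: float = 0.5
    beta: TrueBetaSurface | None = None
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(3))
    alpha: float = 0.0
    family: str = "binomial"
    noise_sd: float = 1.0
    target_lp_sd: float | None = None
    seed: int = 0
    activation: object = None
    log_mean: object = None
    log_sd: object = None

    def __post_init__(self):
        if not (0 <= self.case_fraction <= 1):
            raise ValueError("case_fraction must be in [0, 1]")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        self.gamma = np.asarray(self.gamma, float)
        minute_hours = (np.arange(1, MINUTES_PER_DAY + 1) - 0.5) / 60.0
        act = self.activation or _default_activation
        lm = self.log_mean or _default_log_mean
        ls = self.log_sd or _default_log_sd
        self._pi = {g: np.asarray(act(g, minute_hours), float) for g in (0, 1)}
        self._m = {g: np.asarray(lm(g, minute_hours), float) for g in (0, 1)}
        self._s = {g: np.asarray(ls(g, minute_hours), float) for g in (0, 1)}
        for g in (0, 1):
            if np.any((self._pi[g] < 0) | (self._pi[g] > 1)):
                raise ValueError("activation probabilities must lie in [0, 1]")
            if np.any(self._s[g] <= 0):
                raise ValueError("log-sd curves must be positive")

    def group_of(self, i: int) -> int:
        return int(i >= round(self.n_subjects * (1 - self.case_fraction)))


def simulate_panel(scenario: SyntheticScenario, i: int) -> ActigraphyPanel:
    """Simulate subject ``i``'s day x minute panel (deterministic in seed)."""
    if not (0 <= i < scenario.n_subjects):
        raise ValueError("subject index out of range")
    g = scenario.group_of(i)
    rng = np.random.default_rng([scenario.seed, i])
    shape = (scenario.n_days, MINUTES_PER_DAY)
    active = rng.random(shape) < scenario._pi[g]
    intensity = np.exp(rng.normal(scenario._m[g], scenario._s[g], shape))
    return ActigraphyPanel(f"s{i:04d}", np.where(active, intensity, 0.0))


def simulate_covariates(scenario: SyntheticScenario) -> np.ndarray:
    """Age-like, sex-like, education-like covariates per subject."""
    out = np.empty((scenario.n_subjects, 3))
    for i in range(scenario.n_subjects):
        rng = np.random.default_rng([scenario.seed, i, 1])
        out[i] = [rng.normal(73.0, 7.0), float(rng.random() < 0.5),
                  rng.normal(16.5, 3.2)]
    return out


def functional_term(td_objects: list[TDObject], beta: TrueBetaSurface
                    ) -> np.ndarray:
    """Trapezoid ``\\int\\int Q_i(t,p) beta(t,p) dt dp`` per subject."""
    t = td_objects[0].t_hours
    p = td_objects[0].p_grid
    surf = beta.evaluate(t, p)
    wt = trapezoid_weights(t)
    wp = trapezoid_weights(p)
    kern = (wt[:, None] * surf) * wp[None, :]
    return np.array([float(np.nansum(td.Q * kern)) for td in td_objects])


def simulate_outcomes(
    td_objects: list[TDObject],
    beta: TrueBetaSurface | None,
    Z: np.ndarray,
    gamma,
    alpha: float,
    family: str,
    noise_sd: float,
    seed: int,
    target_lp_sd: float | None = None,
) -> StudyTable:
    """Outcomes drawn forward from the time-by-distribution model.

    ``target_lp_sd`` rescales the functional term so its standard
    deviation across subjects equals the requested designed effect size.
    """
    n = len(td_objects)
    Z = np.atleast_2d(np.asarray(Z, float))
    gamma = np.asarray(gamma, float)
    if beta is None:
        F = np.zeros(n)
    else:
        F = functional_term(td_objects, beta)
        if target_lp_sd is not None:
            sd = F.std()
            if sd > 0:
                F = F * (target_lp_sd / sd)
            F = F - F.mean()
    lp = alpha + (Z @ gamma if gamma.size else 0.0) + F
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    rng = np.random.default_rng([seed, 10_000_019])
    if family == "gaussian":
        y = lp + rng.normal(0.0, noise_sd, n)
    elif family == "binomial":
        y = (rng.random(n) < expit(lp)).astype(float)
    else:
        raise ValueError(f"unknown family {family!r}")
    return StudyTable(
        subject_ids=[td.subject_id for td in td_objects],
        y=y, Z=Z, family=family,
        covariate_names=["age", "sex", "edu"][: Z.shape[1]],
    )


@dataclass
class SimulatedStudy:
    scenario: SyntheticScenario
    panels: list
    td_objects: list
    study: StudyTable
    group: np.ndarray


def simulate_study(scenario: SyntheticScenario, p_grid=None, h: float = 5.0
                   ) -> SimulatedStudy:
    """Full forward simulation: panels -> TD objects -> outcomes."""
    panels = [simulate_panel(scenario, i) for i in range(scenario.n_subjects)]
    tds = [build_td_object(p, p_grid=p_grid, h=h) for p in panels]
    Z = simulate_covariates(scenario) if scenario.gamma.size else \
        np.empty((scenario.n_subjects, 0))
    study = simulate_outcomes(
        tds, scenario.beta, Z, scenario.gamma, scenario.alpha,
        scenario.family, scenario.noise_sd, scenario.seed,
        scenario.target_lp_sd,
    )
    group = np.array([scenario.group_of(i)
                      for i in range(scenario.n_subjects)])
    return SimulatedStudy(scenario, panels, tds, study, group)


def morning_bump_beta(amplitude: float = 1.0) -> TrueBetaSurface:
    """Positive morning / upper-quantile effect (7-10 a.m., p > 0.7)."""
    return TrueBetaSurface("bump", {
        "t_center": 8.5, "t_halfwidth": 2.0,
        "p_center": 0.85, "p_halfwidth": 0.17,
        "amplitude": amplitude,
    })


def strong_signal_scenario(n: int = 400, seed: int = 0, family: str = "binomial",
                           noise_sd: float = 1.0) -> SyntheticScenario:
    """Reference strong-signal scenario: morning upper-quantile bump with
    the designed linear-predictor spread (sd 1.8) giving clearly
    discriminative outcomes."""
    return SyntheticScenario(
        n_subjects=n, beta=morning_bump_beta(), target_lp_sd=1.8,
        family=family, noise_sd=noise_sd, seed=seed,
    )


def null_scenario(n: int = 400, seed: int = 0, family: str = "binomial"
                  ) -> SyntheticScenario:
    """No functional effect, no covariate effect: pure-noise outcomes."""
    return SyntheticScenario(n_subjects=n, beta=None, family=family, seed=seed)


# ---------------------------------------------------------------------------
# curve-level generator for L-moment order selection
# ---------------------------------------------------------------------------


def simulate_lmoment_curve_study(
    n: int = 300,
    t_grid_hours=None,
    signal_order: int = 3,
    snr: float = 3.0,
    seed: int = 0,
):
    """Smooth random L-moment-like curves where one order carries signal.

    Each order r has curves ``L_ir(t) = mean_r(t) + sum_s a_irs phi_s(t)``
    built from three smooth modes; the Gaussian outcome is
    ``y_i = \\int L_i,signal(t) beta(t) dt + e_i`` with a mid-day bump
    effect and noise scaled so var(signal)/var(noise) = snr.  Returns
    ``(curves_by_order, StudyTable, beta_true)``.
    """
    if t_grid_hours is None:
        t_grid_hours = (np.arange(144) * 10 + 5.5) / 60.0
    t = np.asarray(t_grid_hours, float)
    rng = np.random.default_rng([seed, 77])
    modes = np.column_stack([
        np.sin(2 * np.pi * t / 24.0),
        np.cos(2 * np.pi * t / 24.0),
        np.sin(4 * np.pi * t / 24.0),
    ])
    curves = {}
    for r in range(1, 5):
        mean_r = (5.0 / r) * (1 + 0.5 * np.sin(2 * np.pi * (t - 6) / 24))
        a = rng.normal(0.0, [1.0, 0.7, 0.4], size=(n, 3)) / r
        curves[r] = mean_r + a @ modes.T
    beta_true = _cos_bump(t, 13.0, 5.0)          # mid-day effect window
    w = trapezoid_weights(t)
    signal = (curves[signal_order] - curves[signal_order].mean(0)) @ (w * beta_true)
    noise_sd = signal.std() / np.sqrt(snr)
    y = signal + rng.normal(0.0, noise_sd, n)
    study = StudyTable(
        subject_ids=[f"s{i:04d}" for i in range(n)],
        y=y, Z=np.empty((n, 0)), family="gaussian", covariate_names=[],
    )
    return curves, study, beta_true
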