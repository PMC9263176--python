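"""Polynomial and spline bases shared by every regression engine.

Three primitives live here:

* shifted Legendre polynomials on [0, 1], the orthogonal basis that links
  quantile functions to L-moments (``L_r = \\int_0^1 Q(p) P_{r-1}(p) dp``);
* univariate cubic B-spline bases with uniform, degree-repeated knots, used
  for coefficient functions ``beta(t)``, ``beta(p)`` and the tensor surface
  ``beta(t, p)``;
* difference penalties ``D^T D`` for penalized-spline smoothing.

The shifted Legendre polynomial of degree ``r`` is

    P_r(p) = sum_{k=0}^r s_{r,k} p^k,
    s_{r,k} = (-1)^{r-k} C(r, k) C(r+k, k),

with exact integer coefficients; the family is orthogonal on [0, 1] with
``\\int_0^1 P_r P_s dp = delta_{rs} / (2r + 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "shifted_legendre_coeffs",
    "eval_shifted_legendre",
    "LegendreBasis",
    "BSplineBasis",
    "bspline_basis",
    "DifferencePenalty",
    "difference_penalty",
]


def shifted_legendre_coeffs(r: int) -> np.ndarray:
    """Exact integer coefficients ``(s_{r,0}, ..., s_{r,r})`` of ``P_r``.

    Parameters
    ----------
    r
        Polynomial degree, ``r >= 0``.

    Returns
    -------
    numpy.ndarray of object (Python ints), length ``r + 1``, where entry
    ``k`` multiplies ``p**k``.
    """
    if r < 0 or int(r) != r:
        raise ValueError(f"degree r must be a nonnegative integer, got {r}")
    r = int(r)
    coeffs = [
        (-1) ** (r - k) * math.comb(r, k) * math.comb(r + k, k)
        for k in range(r + 1)
    ]
    return np.array(coeffs, dtype=object)


def eval_shifted_legendre(r: int, p) -> np.ndarray | float:
    """Evaluate ``P_r`` at quantile levels ``p`` in [0, 1].

    Uses Horner's scheme on the exact integer coefficients.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("quantile levels p must lie in [0, 1]")
    coeffs = shifted_legendre_coeffs(r)
    out = np.zeros_like(p_arr)
    for c in coeffs[::-1]:
        out = out * p_arr + float(c)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LegendreBasis:
    """Table of shifted Legendre polynomials up to degree ``max_order - 1``."""

    max_order: int

    def __post_init__(self):
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")

    def coeff_table(self) -> list[np.ndarray]:
        return [shifted_legendre_coeffs(r) for r in range(self.max_order)]

    def evaluate(self, p_grid: np.ndarray) -> np.ndarray:
        """Matrix of shape (len(p_grid), max_order), column r-1 is P_{r-1}."""
        p_grid = np.asarray(p_grid, dtype=float)
        return np.column_stack(
            [eval_shifted_legendre(r, p_grid) for r in range(self.max_order)]
        )


# ---------------------------------------------------------------------------
# B-splines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BSplineBasis:
    """Cubic (by default) B-spline basis on a closed interval.

    Knots are equally spaced in the interior with degree-repeated boundary
    knots, so the ``n_basis`` functions form a partition of unity on the
    whole domain.
    """

    domain: tuple[float, float]
    n_basis: int
    degree: int = 3
    knots: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise ValueError(f"invalid domain {self.domain}")
        if self.n_basis < self.degree + 1:
            raise ValueError(
                f"n_basis={self.n_basis} must be >= degree + 1 = {self.degree + 1}"
            )
        n_interior = self.n_basis - self.degree - 1
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        knots = np.concatenate(
            [np.full(self.degree + 1, lo), interior, np.full(self.degree + 1, hi)]
        )
        object.__setattr__(self, "knots", knots)

    def evaluate(self, grid) -> np.ndarray:
        """Design matrix of shape (len(grid), n_basis).

        Rows sum to one everywhere on the domain (boundary included).
        """
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        lo, hi = self.domain
        if np.any(grid < lo - 1e-12) or np.any(grid > hi + 1e-12):
            raise ValueError("evaluation grid extends outside the basis domain")
        grid = np.clip(grid, lo, hi)
        mat = BSpline.design_matrix(grid, self.knots, self.degree).toarray()
        return mat

    def to_dict(self) -> dict:
        return {
            "domain": [float(self.domain[0]), float(self.domain[1])],
            "n_basis": int(self.n_basis),
            "degree": int(self.degree),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineBasis":
        return cls(tuple(d["domain"]), int(d["n_basis"]), int(d["degree"]))


def bspline_basis(domain, n_basis: int, degree: int = 3) -> BSplineBasis:
    """Convenience constructor mirroring :class:`BSplineBasis`."""
    return BSplineBasis(tuple(domain), int(n_basis), int(degree))


# ---------------------------------------------------------------------------
# Difference penalties
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferencePenalty:
    """Order-``d`` difference penalty ``D^T D`` on ``K`` spline coefficients.

    Symmetric positive semidefinite with null-space dimension ``d``
    (constants for d=1; constants and linears for d=2), so polynomial trends
    of degree < d are never shrunk.
    """

    n_coef: int
    order: int = 2

    def __post_init__(self):
        if self.n_coef <= self.order:
            raise ValueError(
                f"need n_coef > order, got n_coef={self.n_coef}, order={self.order}"
            )

    @property
    def matrix(self) -> np.ndarray:
        D = np.diff(np.eye(self.n_coef), n=self.order, axis=0)
        return D.T @ D


def difference_penalty(n_coef: int, order: int = 2) -> DifferencePenalty:
    return DifferencePenalty(int(n_coef), int(order))


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Trapezoid-rule quadrature weights for an increasing grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be 1-D with at least two points")
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w
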