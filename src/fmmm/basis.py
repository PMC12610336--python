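"""Equidistant-knot B-spline bases and the first-difference (RW1) penalty.

All latent functional features are expanded in a common B-spline basis
B(t) = (b_1(t), ..., b_P(t))'.  The knot vector is fully determined by the
domain, the number of basis functions P and the spline order (degree + 1):
interior knots are equidistant, boundary knots repeated ``order`` times.
Smoothing priors on coefficient vectors act through the first-order
random-walk penalty ||D v||^2 with D the (P-1) x P differencing matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BasisSystem", "PenaltyOperator", "make_basis", "eval_design"]


@dataclass(frozen=True)
class BasisSystem:
    """B-spline basis of dimension P with equidistant interior knots."""

    domain: tuple[float, float]
    order: int
    P: int
    knots: np.ndarray = field(repr=False)

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def interior_knots(self) -> np.ndarray:
        return self.knots[self.order : -self.order]


@dataclass(frozen=True)
class PenaltyOperator:
    """First-difference matrix D of shape (P-1, P); D v = 0 iff v is constant."""

    D: np.ndarray

    @property
    def DtD(self) -> np.ndarray:
        return self.D.T @ self.D

    def quadratic_form(self, v: np.ndarray) -> float:
        """sum_p (v_p - v_{p+1})^2 along the last axis."""
        return float(np.sum((self.D @ np.asarray(v, dtype=float)) ** 2))


def make_penalty(P: int) -> PenaltyOperator:
    D = np.zeros((P - 1, P))
    idx = np.arange(P - 1)
    D[idx, idx] = 1.0
    D[idx, idx + 1] = -1.0
    return PenaltyOperator(D=D)


def make_basis(domain: tuple[float, float], P: int, order: int = 4) -> BasisSystem:
    """Construct the equidistant-knot B-spline basis on ``domain``.

    ``P`` basis functions of the given order require ``P - order`` interior
    knots, placed at equal spacing strictly inside the domain; boundary knots
    are repeated ``order`` times so the basis interpolates at the endpoints.
    """
    t0, t1 = float(domain[0]), float(domain[1])
    if not t1 > t0:
        raise ValueError("domain must satisfy T0 < T1")
    if order < 2:
        raise ValueError("order must be >= 2")
    if P < order:
        raise ValueError(f"P ({P}) must be >= order ({order})")
    interior = np.linspace(t0, t1, P - order + 2)[1:-1]
    knots = np.concatenate([np.full(order, t0), interior, np.full(order, t1)])
    return BasisSystem(domain=(t0, t1), order=order, P=P, knots=knots)


def eval_design(basis: BasisSystem, times: np.ndarray) -> np.ndarray:
    """Evaluate the design matrix S of shape (P, n) with columns B(t_j).

    Times must lie within the closed domain; the right endpoint is evaluated
    by the left-limit convention so the last basis function equals 1 at T1.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    t0, t1 = basis.domain
    if np.any(t < t0) or np.any(t > t1):
        out = t[(t < t0) | (t > t1)]
        raise ValueError(f"time(s) outside basis domain [{t0}, {t1}]: {out[:5]}")
    S = BSpline.design_matrix(t, basis.knots, basis.degree, extrapolate=False)
    return np.asarray(S.todense()).T
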