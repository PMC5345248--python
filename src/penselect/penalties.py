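"""Scalar penalty functions, their derivatives, and thresholding operators.

The penalized least-squares objective is

    (1/2n) ||y - X beta||^2  +  sum_j p_lambda(|beta_j|),

and every penalty family here is specified through the scalar function
``p_lambda`` acting on a coefficient magnitude.  With standardized columns
(so each coordinate subproblem has unit curvature) the coordinate-descent
update is the exact univariate minimizer

    argmin_b  (1/2) (z - b)^2 + p_lambda(|b|),

which :func:`threshold` evaluates in closed form for every family.

Families
--------
lasso
    L1 penalty ``lam * |b|`` — soft thresholding; biased for large signals.
elastic_net
    ``lam * (alpha * |b| + (1 - alpha) * b^2)`` — the L1 proportion ``alpha``
    controls the sparsity/grouping trade-off.
scad
    Smoothly clipped absolute deviation; the derivative stays flat at
    ``lam`` up to ``lam``, decays linearly, and vanishes beyond ``a * lam``,
    leaving large coefficients unshrunk (near-unbiasedness).  Requires
    ``a > 2``; the conventional choice from Bayesian risk arguments is 3.7.
mcp
    Minimax concave penalty; the linear decay of the derivative starts at
    the origin, ``p' = (a*lam - t)_+ / a``.  Requires ``a > 1``.
adaptive_lasso
    L1 with per-coefficient weights ``w_j``, usually ``|b_pilot|^-gamma``
    from a pilot estimate; heavily penalizes coordinates the pilot finds
    small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FAMILIES",
    "SCAD_DEFAULT_A",
    "MCP_DEFAULT_A",
    "PenaltySpec",
    "penalty_value",
    "penalty_derivative",
    "threshold",
]

FAMILIES = ("lasso", "elastic_net", "scad", "mcp", "adaptive_lasso")

#: SCAD concavity parameter suggested by Bayesian risk analysis.
SCAD_DEFAULT_A = 3.7
#: MCP concavity parameter; common convention.
MCP_DEFAULT_A = 3.0


@dataclass(frozen=True)
class PenaltySpec:
    """Parameterization of one penalty family.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    lam
        Penalty level lambda, >= 0.
    a
        Concavity parameter; must exceed 2 for SCAD and 1 for MCP.
        Defaults to 3.7 (SCAD) / 3.0 (MCP); ignored by the other families.
    alpha
        Elastic-net L1 proportion in (0, 1]; ignored otherwise.
    weights
        Adaptive-lasso weights, one non-negative (possibly infinite) value
        per coefficient; ignored by the other families.
    """

    family: str
    lam: float
    a: float | None = None
    alpha: float = 1.0
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown penalty family {self.family!r}; expected one of {FAMILIES}"
            )
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lam must be finite and >= 0, got {self.lam}")
        if self.a is None:
            default = {"scad": SCAD_DEFAULT_A, "mcp": MCP_DEFAULT_A}.get(self.family)
            object.__setattr__(self, "a", default)
        if self.family == "scad" and not self.a > 2:
            raise ValueError(f"SCAD requires a > 2, got a={self.a}")
        if self.family == "mcp" and not self.a > 1:
            raise ValueError(f"MCP requires a > 1, got a={self.a}")
        if self.family == "elastic_net" and not (0 < self.alpha <= 1):
            raise ValueError(f"elastic_net requires alpha in (0, 1], got {self.alpha}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(np.isnan(w)) or np.any(w < 0):
                raise ValueError("adaptive weights must be >= 0 and not NaN")
            object.__setattr__(self, "weights", w)

    def with_lam(self, lam: float) -> "PenaltySpec":
        """Copy of this spec at a different penalty level."""
        return PenaltySpec(self.family, lam, a=self.a, alpha=self.alpha, weights=self.weights)


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not np.isfinite(theta) or theta < 0:
        raise ValueError(f"theta must be finite and >= 0, got {theta}")
    return theta


def penalty_value(theta: float, spec: PenaltySpec, weight: float = 1.0) -> float:
    """Penalty p_lambda(theta) for a coefficient magnitude theta >= 0.

    ``weight`` multiplies lambda (adaptive lasso); an infinite weight with
    theta > 0 yields ``inf``, and p(0) = 0 always.
    """
    theta = _check_theta(theta)
    lam, a = spec.lam, spec.a
    if spec.family == "lasso":
        return lam * theta
    if spec.family == "adaptive_lasso":
        if theta == 0.0:
            return 0.0
        return weight * lam * theta
    if spec.family == "elastic_net":
        return lam * (spec.alpha * theta + (1.0 - spec.alpha) * theta * theta)
    if spec.family == "scad":
        if theta <= lam:
            return lam * theta
        if theta <= a * lam:
            return (2.0 * a * lam * theta - theta * theta - lam * lam) / (2.0 * (a - 1.0))
        return 0.5 * (a + 1.0) * lam * lam
    # mcp
    if theta <= a * lam:
        return lam * theta - theta * theta / (2.0 * a)
    return 0.5 * a * lam * lam


def penalty_derivative(theta: float, spec: PenaltySpec, weight: float = 1.0) -> float:
    """Right derivative p'_lambda(theta) at theta >= 0."""
    theta = _check_theta(theta)
    lam, a = spec.lam, spec.a
    if spec.family == "lasso":
        return lam
    if spec.family == "adaptive_lasso":
        return weight * lam
    if spec.family == "elastic_net":
        return lam * (spec.alpha + 2.0 * (1.0 - spec.alpha) * theta)
    if spec.family == "scad":
        if theta <= lam:
            return lam
        return max(a * lam - theta, 0.0) / (a - 1.0)
    # mcp
    return max(a * lam - theta, 0.0) / a


def _soft(z: float, t: float) -> float:
    """Soft-thresholding operator sign(z)(|z| - t)_+."""
    if abs(z) <= t:
        return 0.0
    return math.copysign(abs(z) - t, z)


def threshold(z: float, spec: PenaltySpec, weight: float = 1.0) -> float:
    """Exact minimizer of (1/2)(z - b)^2 + p_lambda(|b|).

    This is the coordinate update for a standardized design (unit diagonal
    of X'X/n).  SCAD and MCP return ``z`` unchanged for |z| >= a*lam — the
    unbiasedness region — while the lasso shrinks every input by lam.
    The SCAD (a > 2) and MCP (a > 1) subproblems are strictly convex at
    unit curvature, so the piecewise formulas are global minimizers.
    """
    z = float(z)
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    lam, a = spec.lam, spec.a
    if spec.family in ("lasso", "adaptive_lasso"):
        if not np.isfinite(weight):
            return 0.0
        return _soft(z, lam * weight)
    if spec.family == "elastic_net":
        return _soft(z, lam * spec.alpha) / (1.0 + 2.0 * lam * (1.0 - spec.alpha))
    if spec.family == "scad":
        az = abs(z)
        if az <= 2.0 * lam:
            return _soft(z, lam)
        if az <= a * lam:
            return ((a - 1.0) * z - math.copysign(a * lam, z)) / (a - 2.0)
        return z
    # mcp
    if abs(z) <= a * lam:
        return _soft(z, lam) * a / (a - 1.0)
    return z
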