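"""Penalized least-squares solvers: cyclic coordinate descent, OLS,
the adaptive-lasso two-stage wrapper, and a stepwise baseline.

All fitting happens on internally standardized covariates (column mean 0,
variance 1) with a centered outcome, so the penalty acts on comparable
scales; reported coefficients and the intercept are back-transformed to
the original scale.  Selection (nonzero pattern) is determined on the
standardized scale, where the thresholding produces exact zeros.

Because n > p throughout, all inner computations use the Gram matrix
G = Xs'Xs / n and moment vector c = Xs'yc / n: a full coordinate-descent
sweep then costs O(p^2) independent of n, and the residual sum of squares
follows from the identity RSS/n = var(y) - 2 c'b + b'Gb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import Dataset
from .penalties import PenaltySpec, penalty_derivative, penalty_value, threshold

__all__ = [
    "FitResult",
    "fit_penalized",
    "fit_ols",
    "fit_adaptive_lasso",
    "fit_stepwise",
    "penalized_objective",
]

logger = logging.getLogger(__name__)

#: Convergence tolerance: maximum absolute coefficient change per sweep.
DEFAULT_TOL = 1e-7
DEFAULT_MAX_SWEEPS = 10_000


@dataclass
class FitResult:
    """Outcome of one model fit, on the original covariate scale."""

    beta: np.ndarray
    intercept: float
    selected: np.ndarray  # indices with beta != 0
    lam: float | None
    bic: float
    n_sweeps: int = 0
    converged: bool = True
    method: str = ""
    #: effective degrees of freedom used in the BIC (equals len(selected)
    #: for OLS-type fits; <= len(selected) for penalized fits)
    df_eff: float = 0.0
    #: objective value per sweep on the standardized scale (only when
    #: fitting with keep_history=True)
    history: list[float] | None = field(default=None, repr=False)
    #: order in which stepwise selection added the surviving variables
    entry_order: list[int] | None = field(default=None, repr=False)

    @property
    def df(self) -> int:
        return len(self.selected)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.beta + self.intercept

    def to_dict(self) -> dict:
        """Full-precision record suitable for JSON export."""
        return {
            "method": self.method,
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "selected": [int(j) for j in self.selected],
            "lam": self.lam,
            "bic": self.bic,
            "df_eff": self.df_eff,
            "n_sweeps": self.n_sweeps,
            "converged": bool(self.converged),
        }


class Standardized:
    """Pre-computed moments of a dataset, shared across an entire lambda path.

    Attributes: ``G`` (p x p, unit diagonal), ``c`` (p,), ``var_y`` (population
    variance of y), ``mu``/``sd`` column moments, ``ybar``, ``n``.
    """

    def __init__(self, data: Dataset):
        X, y = data.X, data.y
        self.n = data.n
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.ybar = y.mean()
        Xs = (X - self.mu) / self.sd
        yc = y - self.ybar
        self.G = Xs.T @ Xs / self.n
        self.c = Xs.T @ yc / self.n
        self.var_y = float(yc @ yc) / self.n

    def rss(self, beta_s: np.ndarray) -> float:
        """Residual sum of squares from the Gram identity (>= 0 clipped)."""
        val = self.var_y - 2.0 * float(self.c @ beta_s) + float(beta_s @ self.G @ beta_s)
        return max(val, 0.0) * self.n


def bic_score(rss: float, n: int, df: float) -> float:
    """BIC(lambda) = n log(RSS/n) + df log(n); df counts nonzero slopes.

    The intercept is in every candidate model, so it is left out of df.
    A perfect fit is floored at RSS/n = 1e-12 to keep the score finite.
    """
    mean_rss = rss / n
    if mean_rss < 1e-12:
        logger.warning("RSS numerically zero; flooring at 1e-12 for BIC")
        mean_rss = 1e-12
    return n * float(np.log(mean_rss)) + df * float(np.log(n))


def effective_df(
    pre: Standardized, beta_s: np.ndarray, spec: PenaltySpec, weights: np.ndarray
) -> float:
    """Effective degrees of freedom of a penalized fit.

    The penalty is locally approximated by the ridge form with diagonal
    D = diag(p'_lambda(|b_j|) / |b_j|) over the selected coordinates, so
    the fit acts like the linear smoother with hat matrix
    X_S (X_S'X_S + n D)^{-1} X_S', whose trace

        df(lambda) = tr[(G_SS + D)^{-1} G_SS]

    is the generalized degrees of freedom used with BIC for these
    penalties.  It reduces to |S| exactly when the penalty derivative
    vanishes on the selected set (e.g. OLS, or SCAD/MCP fits whose
    coefficients all lie in the unbiasedness region).
    """
    S = np.flatnonzero(beta_s)
    if len(S) == 0:
        return 0.0
    b = np.abs(beta_s[S])
    dpen = np.array(
        [penalty_derivative(t, spec, weight=w) for t, w in zip(b, weights[S])]
    )
    Gss = pre.G[np.ix_(S, S)]
    return float(np.trace(np.linalg.solve(Gss + np.diag(dpen / b), Gss)))


def penalized_objective(
    pre: Standardized, beta_s: np.ndarray, spec: PenaltySpec, weights: np.ndarray | None = None
) -> float:
    """Objective (1/2n)||yc - Xs b||^2 + sum_j p_lambda(|b_j|), standardized scale."""
    w = np.ones(len(beta_s)) if weights is None else weights
    pen = sum(
        penalty_value(abs(b), spec, weight=wj)
        for b, wj in zip(beta_s, w)
        if b != 0.0 or np.isfinite(wj)
    )
    return 0.5 * pre.rss(beta_s) / pre.n + pen


def _resolve_weights(spec: PenaltySpec, p: int) -> np.ndarray:
    if spec.family == "adaptive_lasso":
        if spec.weights is None or len(spec.weights) != p:
            raise ValueError("adaptive_lasso requires a length-p weights vector")
        return spec.weights
    return np.ones(p)


def fit_penalized(
    data: Dataset,
    spec: PenaltySpec,
    init: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_sweeps: int = DEFAULT_MAX_SWEEPS,
    pre: Standardized | None = None,
    keep_history: bool = False,
    bic_variant: str = "effective",
) -> FitResult:
    """Cyclic coordinate descent for the penalized least-squares objective.

    Parameters
    ----------
    data
        The dataset; columns are standardized internally.
    spec
        Penalty family and parameters.
    init
        Optional warm-start coefficients on the *original* covariate scale.
    pre
        Optional pre-computed :class:`Standardized` moments (shared across a
        lambda path); computed from ``data`` when omitted.
    bic_variant
        ``"effective"`` (default) scores the fit with the generalized
        degrees of freedom of :func:`effective_df`; ``"count"`` uses the
        raw number of nonzero coefficients.

    Returns
    -------
    FitResult
        Coefficients on the original scale; ``converged=False`` (not an
        exception) if ``max_sweeps`` cyclic sweeps did not reach ``tol``.
    """
    if pre is None:
        pre = Standardized(data)
    p = data.p
    G, c = pre.G, pre.c
    w = _resolve_weights(spec, p)

    beta = np.zeros(p) if init is None else np.asarray(init, float) * pre.sd
    # coordinates with infinite adaptive weight are pinned at zero
    beta[~np.isfinite(w)] = 0.0

    history: list[float] | None = [penalized_objective(pre, beta, spec, w)] if keep_history else None
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        delta = 0.0
        for j in range(p):
            bj = beta[j]
            if not np.isfinite(w[j]):
                continue
            # partial residual correlation: z_j = c_j - G[j]·beta + beta_j
            z = c[j] - float(G[j] @ beta) + bj
            new = threshold(z, spec, weight=w[j])
            if new != bj:
                beta[j] = new
                change = abs(new - bj)
                if change > delta:
                    delta = change
        if history is not None:
            history.append(penalized_objective(pre, beta, spec, w))
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("coordinate descent did not converge in %d sweeps", max_sweeps)

    selected = np.flatnonzero(beta)
    rss = pre.rss(beta)
    if bic_variant == "effective":
        df = effective_df(pre, beta, spec, w)
    elif bic_variant == "count":
        df = float(len(selected))
    else:
        raise ValueError(f"bic_variant must be 'effective' or 'count', got {bic_variant!r}")
    beta_orig = beta / pre.sd
    intercept = pre.ybar - float(pre.mu @ beta_orig)
    return FitResult(
        beta=beta_orig,
        intercept=intercept,
        selected=selected,
        lam=spec.lam,
        bic=bic_score(rss, pre.n, df),
        n_sweeps=sweep,
        converged=converged,
        method=spec.family,
        df_eff=df,
        history=history,
    )


def _ols_on_support(pre: Standardized, support: np.ndarray) -> tuple[np.ndarray, float]:
    """Standardized-scale OLS coefficients on a support and the resulting RSS."""
    if len(support) == 0:
        return np.zeros(0), pre.var_y * pre.n
    Gss = pre.G[np.ix_(support, support)]
    try:
        chol = np.linalg.cholesky(Gss)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"rank-deficient design on support {support.tolist()}"
        ) from exc
    b = np.linalg.solve(chol.T, np.linalg.solve(chol, pre.c[support]))
    rss = max(pre.var_y - float(pre.c[support] @ b), 0.0) * pre.n
    return b, rss


def fit_ols(
    data: Dataset,
    support: np.ndarray | list[int] | None = None,
    pre: Standardized | None = None,
) -> FitResult:
    """Exact least squares restricted to ``support`` (all columns if omitted).

    The oracle estimator of a simulation replicate is ``fit_ols`` on the
    true support.  An empty support returns the intercept-only model.
    """
    if pre is None:
        pre = Standardized(data)
    p = len(pre.sd)
    support = np.arange(p) if support is None else np.asarray(sorted(support), dtype=int)
    if len(support) and (support.min() < 0 or support.max() >= p):
        raise ValueError("support indices out of range")
    if len(support) >= pre.n:
        raise ValueError("support size must be < n")
    b_s, rss = _ols_on_support(pre, support)
    beta = np.zeros(p)
    beta[support] = b_s / pre.sd[support]
    intercept = pre.ybar - float(pre.mu @ beta)
    return FitResult(
        beta=beta,
        intercept=intercept,
        selected=np.flatnonzero(beta),
        lam=None,
        bic=bic_score(rss, pre.n, len(support)),
        method="ols",
        df_eff=float(len(support)),
    )


def pilot_weights(data: Dataset, gamma: float = 1.0, pre: Standardized | None = None) -> np.ndarray:
    """Adaptive-lasso weights |b_pilot|^-gamma from the full OLS pilot.

    Weights are computed from the *standardized* pilot coefficients so they
    are unit-free; an exactly zero pilot coefficient maps to an infinite
    weight, excluding that coordinate.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    if pre is None:
        pre = Standardized(data)
    pilot = fit_ols(data, pre=pre)
    b_std = np.abs(pilot.beta * pre.sd)
    with np.errstate(divide="ignore"):
        return np.where(b_std > 0, b_std**-gamma, np.inf)


def fit_adaptive_lasso(
    data: Dataset,
    lam: float,
    gamma: float = 1.0,
    pre: Standardized | None = None,
    **kwargs,
) -> FitResult:
    """Two-stage adaptive lasso: full-OLS pilot, then weighted L1 fit."""
    if pre is None:
        pre = Standardized(data)
    w = pilot_weights(data, gamma=gamma, pre=pre)
    spec = PenaltySpec("adaptive_lasso", lam, weights=w)
    res = fit_penalized(data, spec, pre=pre, **kwargs)
    res.method = "adaptive_lasso"
    return res


def _pvalues_on_support(pre: Standardized, support: np.ndarray) -> np.ndarray:
    """Two-sided t-test p-values for each slope in the OLS fit on support."""
    k = len(support)
    Gss = pre.G[np.ix_(support, support)]
    Ginv = np.linalg.inv(Gss)
    b = Ginv @ pre.c[support]
    rss = max(pre.var_y - float(pre.c[support] @ b), 0.0) * pre.n
    dof = pre.n - k - 1
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * np.diag(Ginv) / pre.n)
    t = b / se
    return 2.0 * stats.t.sf(np.abs(t), dof)


def fit_stepwise(
    data: Dataset,
    criterion: str = "bic",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    pre: Standardized | None = None,
) -> FitResult:
    """Bidirectional stepwise selection, returning OLS on the final support.

    ``criterion="bic"`` adds/drops whichever move lowers BIC the most and
    stops when no move improves it.  ``criterion="pvalue"`` uses classical
    enter/remove p-value thresholds (requires ``p_enter <= p_remove``).
    Deterministic: ties are broken toward the lowest column index.
    """
    if criterion not in ("bic", "pvalue"):
        raise ValueError(f"criterion must be 'bic' or 'pvalue', got {criterion!r}")
    if criterion == "pvalue" and p_enter > p_remove:
        raise ValueError("pvalue mode requires p_enter <= p_remove")
    if pre is None:
        pre = Standardized(data)
    p = len(pre.sd)
    support: list[int] = []
    entry_order: list[int] = []

    def bic_of(sup: list[int]) -> float:
        _, rss = _ols_on_support(pre, np.asarray(sup, dtype=int))
        return bic_score(rss, pre.n, len(sup))

    if criterion == "bic":
        current = bic_of(support)
        while True:
            moved = False
            # forward: best single addition
            best_j, best_val = -1, current
            for j in range(p):
                if j in support:
                    continue
                val = bic_of(support + [j])
                if val < best_val - 1e-10:
                    best_j, best_val = j, val
            if best_j >= 0:
                support.append(best_j)
                entry_order.append(best_j)
                current = best_val
                moved = True
            # backward: drop while it improves
            while support:
                best_j, best_val = -1, current
                for j in support:
                    val = bic_of([k for k in support if k != j])
                    if val < best_val - 1e-10:
                        best_j, best_val = j, val
                if best_j < 0:
                    break
                support.remove(best_j)
                entry_order.remove(best_j)
                current = best_val
                moved = True
            if not moved:
                break
    else:
        while True:
            moved = False
            best_j, best_p = -1, p_enter
            for j in range(p):
                if j in support:
                    continue
                sup = np.asarray(sorted(support + [j]), dtype=int)
                pv = _pvalues_on_support(pre, sup)[int(np.searchsorted(sup, j))]
                if pv < best_p - 1e-15:
                    best_j, best_p = j, pv
            if best_j >= 0:
                support.append(best_j)
                entry_order.append(best_j)
                moved = True
            while support:
                sup = np.asarray(sorted(support), dtype=int)
                pv = _pvalues_on_support(pre, sup)
                worst = int(np.argmax(pv))
                if pv[worst] <= p_remove:
                    break
                support.remove(int(sup[worst]))
                entry_order.remove(int(sup[worst]))
                moved = True
            if not moved:
                break

    res = fit_ols(data, support=np.asarray(sorted(support), dtype=int), pre=pre)
    res.method = "stepwise"
    res.entry_order = entry_order
    return res
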