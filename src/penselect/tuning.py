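"""Lambda-path construction and BIC-based tuning-parameter selection.

The penalty level lambda regulates sparsity: at lambda = 0 every variable
is selected (OLS), and for large enough lambda none is.  We fit a
log-spaced path of 100 lambda values from the smallest empty-model lambda
down to 0.001 of it, warm-starting each fit from the previous solution,
and pick the fit minimizing

    BIC(lambda) = n log(RSS/n) + df(lambda) log(n),

the criterion under which these penalized estimators are selection-
consistent.  By default df(lambda) is the generalized degrees of freedom
of the penalized smoother (see :func:`penselect.solver.effective_df`), the
form used in the SCAD tuning literature; ``bic_variant="count"`` swaps in
the raw nonzero count.  For the elastic net the L1 proportion alpha is
grid-searched over {0.1, ..., 0.9} jointly with lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .penalties import PenaltySpec
from .solver import (
    FitResult,
    Standardized,
    fit_ols,
    fit_penalized,
    fit_stepwise,
    pilot_weights,
)

__all__ = [
    "PathResult",
    "lambda_path",
    "select_by_bic",
    "fit_method",
    "METHODS",
    "DEFAULT_N_LAMS",
    "DEFAULT_RATIO",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_N_LAMS = 100
DEFAULT_RATIO = 1e-3
DEFAULT_ALPHA_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))

#: Method identifiers accepted by :func:`fit_method` and the study driver.
METHODS = ("stepwise", "elastic_net", "lasso", "mcp", "scad", "adaptive_lasso", "ols")


@dataclass
class PathResult:
    """A fitted lambda path with its BIC-selected index."""

    lams: np.ndarray
    fits: list[FitResult]
    best_index: int
    alpha_grid: tuple[float, ...] | None = None
    alpha: float | None = None

    @property
    def best(self) -> FitResult:
        return self.fits[self.best_index]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lambda": self.lams,
                "df": [f.df for f in self.fits],
                "bic": [f.bic for f in self.fits],
                "selected_count": [f.df for f in self.fits],
            }
        )


def _lambda_max(pre: Standardized, spec_template: PenaltySpec) -> float:
    """Smallest lambda at which the all-zero solution is stationary."""
    z = np.abs(pre.c)
    if pre.var_y <= 0:
        raise ValueError("outcome has zero variance")
    if spec_template.family == "elastic_net":
        return float(z.max()) / spec_template.alpha
    if spec_template.family == "adaptive_lasso":
        w = spec_template.weights
        if w is None:
            raise ValueError("adaptive_lasso template needs weights for the path")
        finite = np.isfinite(w)
        if not finite.any():
            raise ValueError("all adaptive weights are infinite")
        if np.any(w[finite] == 0):
            # an unpenalized coordinate is active at every lambda
            return float(z.max())
        return float((z[finite] / w[finite]).max())
    # lasso, scad, mcp share the soft-threshold zero condition at the origin
    return float(z.max())


def lambda_path(
    data: Dataset,
    spec_template: PenaltySpec,
    n_lams: int = DEFAULT_N_LAMS,
    ratio: float = DEFAULT_RATIO,
    pre: Standardized | None = None,
) -> np.ndarray:
    """Strictly decreasing log-spaced grid from lambda_max to ratio*lambda_max."""
    if n_lams < 2:
        raise ValueError("n_lams must be >= 2")
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    if pre is None:
        pre = Standardized(data)
    lam_max = _lambda_max(pre, spec_template)
    return np.geomspace(lam_max, ratio * lam_max, n_lams)


def _fit_path(
    data: Dataset,
    spec_template: PenaltySpec,
    n_lams: int,
    ratio: float,
    pre: Standardized,
    bic_variant: str = "effective",
) -> PathResult:
    lams = lambda_path(data, spec_template, n_lams, ratio, pre=pre)
    fits: list[FitResult] = []
    warm: np.ndarray | None = None
    for lam in lams:
        fit = fit_penalized(
            data, spec_template.with_lam(lam), init=warm, pre=pre, bic_variant=bic_variant
        )
        fits.append(fit)
        warm = fit.beta
    bics = np.array([f.bic for f in fits])
    best = int(np.argmin(bics))  # first minimum = largest lambda = sparsest
    return PathResult(lams=lams, fits=fits, best_index=best)


def select_by_bic(
    data: Dataset,
    spec_template: PenaltySpec,
    n_lams: int = DEFAULT_N_LAMS,
    ratio: float = DEFAULT_RATIO,
    alpha_grid: tuple[float, ...] | None = None,
    pre: Standardized | None = None,
    bic_variant: str = "effective",
) -> PathResult:
    """Fit the whole path with warm starts and return the BIC minimizer.

    Ties in BIC resolve toward the larger lambda (sparser model).  For the
    elastic net, every alpha in ``alpha_grid`` (default {0.1, ..., 0.9})
    gets its own lambda path and the global BIC minimum wins.
    """
    if pre is None:
        pre = Standardized(data)
    if spec_template.family != "elastic_net":
        return _fit_path(data, spec_template, n_lams, ratio, pre, bic_variant)

    grid = tuple(alpha_grid) if alpha_grid is not None else DEFAULT_ALPHA_GRID
    best_path: PathResult | None = None
    for alpha in grid:
        tmpl = PenaltySpec("elastic_net", 1.0, alpha=alpha)
        path = _fit_path(data, tmpl, n_lams, ratio, pre, bic_variant)
        path.alpha = alpha
        if best_path is None or path.best.bic < best_path.best.bic:
            best_path = path
    best_path.alpha_grid = grid
    return best_path


def fit_method(
    data: Dataset,
    method: str,
    n_lams: int = DEFAULT_N_LAMS,
    ratio: float = DEFAULT_RATIO,
    gamma: float = 1.0,
    scad_a: float | None = None,
    mcp_a: float | None = None,
    pre: Standardized | None = None,
    bic_variant: str = "effective",
) -> FitResult:
    """Fit one named method with its tuning fully resolved (BIC where needed).

    ``method`` is one of :data:`METHODS`; the oracle (OLS on the true
    support) lives in the simulation driver because it needs the truth.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if pre is None:
        pre = Standardized(data)
    if method == "ols":
        return fit_ols(data, pre=pre)
    if method == "stepwise":
        return fit_stepwise(data, criterion="bic", pre=pre)
    if method == "adaptive_lasso":
        w = pilot_weights(data, gamma=gamma, pre=pre)
        tmpl = PenaltySpec("adaptive_lasso", 1.0, weights=w)
    elif method == "scad":
        tmpl = PenaltySpec("scad", 1.0, a=scad_a)
    elif method == "mcp":
        tmpl = PenaltySpec("mcp", 1.0, a=mcp_a)
    elif method == "elastic_net":
        tmpl = PenaltySpec("elastic_net", 1.0, alpha=0.5)
    else:
        tmpl = PenaltySpec("lasso", 1.0)
    res = select_by_bic(data, tmpl, n_lams=n_lams, ratio=ratio, pre=pre, bic_variant=bic_variant).best
    res.method = method
    return res
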