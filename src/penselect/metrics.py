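"""Model-error and selection metrics against a known truth.

For an estimate b of the true coefficient vector beta with regressor
covariance Sigma, the model error is the quadratic form

    ME(b) = (b - beta)' Sigma (b - beta),

i.e. the population mean-squared prediction-surface error.  The relative
model error RME divides by the ME of the full-model OLS estimator, and
MRME is the median RME over replicates, reported as a percentage.  TP/FP
count correctly and incorrectly selected covariates ("selected" meaning a
nonzero estimated coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReplicateResult",
    "model_error",
    "relative_model_error",
    "selection_metrics",
    "mrme",
]


@dataclass
class ReplicateResult:
    """Per-replicate metrics for one method."""

    method: str
    rep: int
    me: float
    rme: float
    tp: int
    fp: int
    converged: bool = True


def model_error(beta_hat: np.ndarray, beta_true: np.ndarray, sigma: np.ndarray) -> float:
    """Quadratic-form model error (b - beta)' Sigma (b - beta)."""
    beta_hat = np.asarray(beta_hat, float)
    beta_true = np.asarray(beta_true, float)
    sigma = np.asarray(sigma, float)
    p = len(beta_true)
    if beta_hat.shape != (p,) or sigma.shape != (p, p):
        raise ValueError(
            f"dimension mismatch: beta_hat {beta_hat.shape}, beta_true {beta_true.shape}, "
            f"sigma {sigma.shape}"
        )
    d = beta_hat - beta_true
    return float(d @ sigma @ d)


def relative_model_error(me_method: float, me_fullols: float) -> float:
    """RME = ME(method) / ME(full OLS)."""
    if me_fullols <= 0:
        raise ValueError("full-OLS model error must be > 0 (degenerate noiseless replicate)")
    return me_method / me_fullols


def selection_metrics(selected, beta_true: np.ndarray) -> tuple[int, int]:
    """(TP, FP): counts of truly-nonzero and truly-zero covariates selected."""
    beta_true = np.asarray(beta_true, float)
    sel = np.asarray(sorted(set(int(j) for j in selected)), dtype=int)
    if len(sel) and (sel.min() < 0 or sel.max() >= len(beta_true)):
        raise ValueError("selected indices out of range")
    truth = beta_true != 0
    tp = int(truth[sel].sum()) if len(sel) else 0
    return tp, len(sel) - tp


def mrme(rmes) -> float:
    """Median relative model error as a percentage (two-decimal convention)."""
    return 100.0 * float(np.median(np.asarray(list(rmes), float)))
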