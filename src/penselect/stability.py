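"""Bootstrap selection-frequency analysis.

A variable-selection result on a single dataset says nothing about how
stable that selection is.  Here each method is refit from scratch — fresh
lambda path and BIC minimization — on ``n_boot`` with-replacement
resamples of the rows, and each variable's selection frequency is the
fraction of resamples in which its coefficient is nonzero.  The sign
reported for a variable comes from the full-data fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .tuning import fit_method

__all__ = ["StabilityReport", "bootstrap_selection", "render_selection_table"]

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    """Per-variable bootstrap selection frequencies for one method."""

    method: str
    n_boot: int
    names: list[str]
    selected_full: np.ndarray  # bool, full-data selection
    sign: list[str]  # "+", "-", or "" per variable (full-data fit)
    freq: np.ndarray  # selection fraction over resamples
    coef_full: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "variable": self.names,
                "sign": self.sign,
                "freq": self.freq,
                "selected_full": self.selected_full,
                "coefficient": self.coef_full,
            }
        )


def bootstrap_selection(
    data: Dataset,
    method: str,
    n_boot: int = 100,
    seed: int = 0,
    refit_lambda: bool = True,
    **fit_kwargs,
) -> StabilityReport:
    """Selection frequencies for one method over bootstrap resamples.

    The tuning parameter is re-selected inside every resample by default
    (``refit_lambda=True``), treating tuning as part of the procedure whose
    stability is being measured; ``refit_lambda=False`` freezes the
    full-data lambda instead.  A resample that produces a constant column
    is redrawn once, then skipped with a log entry.  Deterministic given
    ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    full = fit_method(data, method, **fit_kwargs)
    sign = ["+" if b > 0 else "-" if b < 0 else "" for b in full.beta]

    def refit(boot: Dataset):
        if refit_lambda or full.lam is None:
            return fit_method(boot, method, **fit_kwargs)
        # frozen-lambda mode: re-fit at the full-data lambda
        from .penalties import PenaltySpec
        from .solver import fit_adaptive_lasso, fit_penalized

        if method == "adaptive_lasso":
            return fit_adaptive_lasso(boot, full.lam, gamma=fit_kwargs.get("gamma", 1.0))
        alpha = 0.5 if method == "elastic_net" else 1.0
        return fit_penalized(boot, PenaltySpec(method, full.lam, alpha=alpha))

    rng = np.random.default_rng(seed)
    counts = np.zeros(data.p)
    done = 0
    for b in range(n_boot):
        boot = None
        for attempt in range(2):
            rows = rng.integers(0, data.n, data.n)
            try:
                boot = data.subsample(rows)
                break
            except ValueError:
                continue
        if boot is None:
            logger.warning("bootstrap resample %d degenerate twice; skipped", b)
            continue
        fit = refit(boot)
        counts[fit.selected] += 1
        done += 1
    if done == 0:
        raise RuntimeError("all bootstrap resamples degenerate")
    return StabilityReport(
        method=method,
        n_boot=done,
        names=list(data.names),
        selected_full=full.beta != 0,
        sign=sign,
        freq=counts / done,
        coef_full=full.beta.copy(),
    )


def render_selection_table(reports: list[StabilityReport]) -> str:
    """Fixed-width text table: one row per variable selected at least once.

    Cells show the full-data coefficient sign with the bootstrap selection
    frequency in parentheses, e.g. ``+ (0.98)``; a variable selected only
    in resamples (never on the full data) shows the bare frequency; an
    empty cell means the method never selected it.  Output is byte-stable
    for a fixed seed, so it can be regression-tested.
    """
    if not reports:
        raise ValueError("no reports given")
    names = reports[0].names
    for r in reports[1:]:
        if r.names != names:
            raise ValueError("reports cover different variable lists")

    def cell(r: StabilityReport, j: int) -> str:
        if r.selected_full[j]:
            return f"{r.sign[j]} ({r.freq[j]:.2f})"
        if r.freq[j] > 0:
            return f"({r.freq[j]:.2f})"
        return ""

    keep = [
        j
        for j in range(len(names))
        if any(r.selected_full[j] or r.freq[j] > 0 for r in reports)
    ]
    headers = ["variable"] + [r.method for r in reports]
    rows = [[names[j]] + [cell(r, j) for r in reports] for j in keep]
    widths = [max(len(h), *(len(row[k]) for row in rows)) if rows else len(h) for k, h in enumerate(headers)]
    lines = ["  ".join(h.ljust(w) for h, w in zip(headers, widths)).rstrip()]
    lines.append("  ".join("-" * w for w in widths))
    for row in rows:
        lines.append("  ".join(v.ljust(w) for v, w in zip(row, widths)).rstrip())
    return "\n".join(lines) + "\n"
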