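"""Tabular dataset container shared by every solver and study stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """A complete-case design matrix with a continuous outcome.

    Attributes
    ----------
    X
        n x p covariate matrix (subjects by covariates), no missing values.
    y
        Length-n continuous outcome.
    names
        p covariate labels, aligned with the columns of ``X``.
    outcome_name
        Label for ``y`` (used when writing CSV).
    """

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    outcome_name: str = "y"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.names = list(self.names)
        if self.X.ndim != 2:
            raise ValueError("X must be two-dimensional")
        n, p = self.X.shape
        if len(self.y) != n:
            raise ValueError(f"X has {n} rows but y has {len(self.y)} entries")
        if len(self.names) != p:
            raise ValueError(f"X has {p} columns but {len(self.names)} names given")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("X and y must be finite with no missing values")
        if n <= p:
            raise ValueError(f"need n > p (got n={n}, p={p})")
        sd = self.X.std(axis=0)
        if np.any(sd == 0):
            bad = [self.names[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant column(s): {bad}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path, outcome: str) -> "Dataset":
        """Read a dataset from CSV (header row of names, one outcome column).

        Lines starting with ``#`` (provenance headers) are skipped.
        """
        df = pd.read_csv(path, comment="#")
        if outcome not in df.columns:
            raise ValueError(f"outcome column {outcome!r} not found in {path}")
        bad = df.columns[df.dtypes == object]
        if len(bad):
            raise ValueError(f"non-numeric column(s) in {path}: {list(bad)}")
        if df.isna().any().any():
            rows = df.index[df.isna().any(axis=1)][:5].tolist()
            raise ValueError(f"missing values in {path} (first rows: {rows})")
        names = [c for c in df.columns if c != outcome]
        return cls(df[names].to_numpy(float), df[outcome].to_numpy(float), names, outcome)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df[self.outcome_name] = self.y
        return df

    def to_csv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        """Write the dataset; optional ``#``-prefixed provenance lines first."""
        with open(path, "w", newline="") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)

    def subsample(self, rows: np.ndarray) -> "Dataset":
        """Row-indexed resample (used by the bootstrap); validates anew."""
        return Dataset(self.X[rows], self.y[rows], self.names, self.outcome_name)
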