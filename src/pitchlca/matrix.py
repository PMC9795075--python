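"""Categorical response matrices: N observation sequences of per-trial outcome codes.

One observation unit is a participant x condition block (a row of J trials).
Outcome codes follow the standard convention: 1 = opposing, 2 = following,
3 = nonresponse, 4 = error. The number of categories actually observed at each
trial column (``Kj``) drives the latent-class parameter count, so the container
tracks per-column category sets rather than assuming all four codes occur.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: canonical outcome coding
OUTCOME_CODES = {"opposing": 1, "following": 2, "nonresponse": 3, "error": 4}
CODE_OUTCOMES = {v: k for k, v in OUTCOME_CODES.items()}

#: stimulus-direction covariate coding (down-only = 1, up-only = 2, random = 3)
DIRECTION_CODES = {"down_only": 1, "up_only": 2, "random": 3}


class ResponseMatrix:
    """N x J matrix of categorical per-trial outcomes with optional covariate.

    Parameters
    ----------
    Y : array-like of int, shape (N, J)
        Outcome codes; each entry must be one of 1..4 (missing trials are not
        representable here — they are resolved upstream).
    covariate : array-like of float, shape (N,), optional
        Per-observation numeric covariate (stimulus-direction code).
    row_ids : sequence of str, optional
        Observation identifiers (e.g. ``"p03:down_only"``).
    conditions : sequence of str, optional
        Condition label per row.
    """

    def __init__(self, Y, covariate=None, row_ids=None, conditions=None):
        Y = np.asarray(Y, dtype=int)
        if Y.ndim != 2 or Y.size == 0:
            raise ValueError("Y must be a non-empty 2-D array of outcome codes")
        if Y.min() < 1 or Y.max() > 4:
            raise ValueError("outcome codes must lie in 1..4")
        self.Y = Y
        self.covariate = None if covariate is None else np.asarray(covariate, dtype=float)
        if self.covariate is not None and self.covariate.shape != (Y.shape[0],):
            raise ValueError("covariate must have one entry per row")
        self.row_ids = list(row_ids) if row_ids is not None else [str(i) for i in range(Y.shape[0])]
        self.conditions = list(conditions) if conditions is not None else None

    @property
    def N(self) -> int:
        return self.Y.shape[0]

    @property
    def J(self) -> int:
        return self.Y.shape[1]

    @property
    def column_categories(self) -> list[np.ndarray]:
        """Sorted codes actually observed at each column (defines Kj)."""
        return [np.unique(self.Y[:, j]) for j in range(self.J)]

    @property
    def Kj(self) -> np.ndarray:
        return np.array([len(c) for c in self.column_categories])

    def encoded(self) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (Yidx, categories): Yidx[i, j] is the 0-based index of
        Y[i, j] within the column's observed category list."""
        cats = self.column_categories
        Yidx = np.empty_like(self.Y)
        for j, c in enumerate(cats):
            Yidx[:, j] = np.searchsorted(c, self.Y[:, j])
        return Yidx, cats

    def subset_columns(self, start: int, stop: int) -> "ResponseMatrix":
        """Column block [start, stop) as a new matrix (phase-wise fits)."""
        return ResponseMatrix(
            self.Y[:, start:stop],
            covariate=self.covariate,
            row_ids=self.row_ids,
            conditions=self.conditions,
        )

    # ---------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.row_ids})
        if self.conditions is not None:
            df["condition"] = self.conditions
        if self.covariate is not None:
            df["direction_code"] = self.covariate
        for j in range(self.J):
            df[f"y{j + 1}"] = self.Y[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseMatrix":
        ycols = [c for c in df.columns if c.startswith("y") and c[1:].isdigit()]
        ycols.sort(key=lambda c: int(c[1:]))
        return cls(
            df[ycols].to_numpy(dtype=int),
            covariate=df["direction_code"].to_numpy(float) if "direction_code" in df else None,
            row_ids=df["id"].astype(str).tolist() if "id" in df else None,
            conditions=df["condition"].tolist() if "condition" in df else None,
        )

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        return cls.from_frame(pd.read_csv(Path(path)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"ResponseMatrix(N={self.N}, J={self.J}, Kj={self.Kj.tolist()})"
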