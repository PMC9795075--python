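"""Descriptive outputs: response-type count tables, trial-to-trial transition
counts (Sankey/alluvial input), and per-class acoustic summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import CODE_OUTCOMES, ResponseMatrix

TYPES = ("opposing", "following", "nonresponse", "error")


def round_half_up_percent(x: float) -> int:
    """Integer percent with exact half-up rounding (printed-table convention)."""
    return int(np.floor(100.0 * x + 0.5))


def matrix_to_counts(matrix: ResponseMatrix) -> pd.DataFrame:
    """Long-format per-trial, per-condition response-type counts."""
    if matrix.conditions is None:
        raise ValueError("matrix rows must carry condition labels")
    rows = []
    conds = np.asarray(matrix.conditions)
    for cond in pd.unique(conds):
        sub = matrix.Y[conds == cond]
        for j in range(matrix.J):
            counts = {t: int(np.sum(sub[:, j] == k + 1)) for k, t in enumerate(TYPES)}
            rows.append({"condition": cond, "trial": j + 1, **counts})
    return pd.DataFrame(rows)


class CountTable:
    """Per-trial counts plus condition-wise and pooled proportion rows."""

    def __init__(self, counts: pd.DataFrame):
        required = {"condition", "trial", *TYPES}
        if not required.issubset(counts.columns):
            raise ValueError(f"counts table must have columns {sorted(required)}")
        self.counts = counts.sort_values(["condition", "trial"]).reset_index(drop=True)

    @classmethod
    def from_matrix(cls, matrix: ResponseMatrix) -> "CountTable":
        return cls(matrix_to_counts(matrix))

    def condition_totals(self) -> pd.DataFrame:
        return self.counts.groupby("condition")[list(TYPES)].sum()

    def proportions(self) -> pd.DataFrame:
        """Integer-percent response-type proportions per condition and pooled
        ('total' row), each type's column total over the condition's grand
        total, rounded half up."""
        totals = self.condition_totals()
        pooled = totals.sum(axis=0).to_frame().T
        pooled.index = pd.Index(["total"], name="condition")
        both = pd.concat([totals, pooled])
        grand = both.sum(axis=1)
        return both.apply(
            lambda col: [round_half_up_percent(v / g) for v, g in zip(col, grand)])

    def proportion(self, condition: str, response_type: str) -> int:
        """One printed percentage, e.g. ('total', 'opposing') -> pooled
        opposing percent."""
        return int(self.proportions().loc[condition, response_type])


def count_table(matrix_or_counts) -> CountTable:
    if isinstance(matrix_or_counts, ResponseMatrix):
        return CountTable.from_matrix(matrix_or_counts)
    return CountTable(matrix_or_counts)


def transition_table(matrix: ResponseMatrix, labels=None,
                     class_names=None) -> pd.DataFrame:
    """4 x 4 response-type flow counts for every adjacent trial pair.

    Returns a long-format table (step, from, to, class, count) where step j
    covers the transition trial j -> j+1; class 'all' pools every observation
    and, when modal class labels are given, one stratum per class is added.
    """
    if matrix.J < 2:
        raise ValueError("need at least two trials to count transitions")
    Y = matrix.Y
    strata = {"all": np.ones(matrix.N, dtype=bool)}
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            name = class_names[lab] if class_names is not None else f"class_{lab + 1}"
            strata[name] = labels == lab
    rows = []
    for name, mask in strata.items():
        sub = Y[mask]
        for j in range(matrix.J - 1):
            pair = sub[:, j] * 10 + sub[:, j + 1]
            for a in range(1, 5):
                for b in range(1, 5):
                    c = int(np.sum(pair == a * 10 + b))
                    if c:
                        rows.append({
                            "step": j + 1,
                            "from": CODE_OUTCOMES[a],
                            "to": CODE_OUTCOMES[b],
                            "class": name,
                            "count": c,
                        })
    return pd.DataFrame(rows, columns=["step", "from", "to", "class", "count"])


def acoustic_summary(measures: pd.DataFrame, labels: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Mean and SE of onset time, peak time and absolute peak amplitude by
    latent class x stimulus direction x response type.

    ``measures`` is the long-format table from trial processing; ``labels``
    optionally maps (participant_id, condition) -> class_name (otherwise a
    single 'all' class). SE is the sample SD over trial-level values divided
    by sqrt(n); cells with no trials stay absent, with n = 1 the SE is NaN.
    """
    df = measures[measures["response_type"].isin(["opposing", "following"])].copy()
    if labels is not None:
        df = df.merge(labels[["participant_id", "condition", "class_name"]],
                      on=["participant_id", "condition"], how="left")
        df["class_name"] = df["class_name"].fillna("unassigned")
    else:
        df["class_name"] = "all"
    out = []
    keys = ["class_name", "shift_direction", "response_type"]
    for names, g in df.groupby(keys, sort=True):
        row = dict(zip(keys, names))
        for col in ("onset_time", "peak_time", "peak_amplitude"):
            vals = g[col].dropna()
            n = len(vals)
            row[f"{col}_mean"] = vals.mean() if n else np.nan
            row[f"{col}_se"] = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            row[f"{col}_n"] = n
        out.append(row)
    return pd.DataFrame(out)
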