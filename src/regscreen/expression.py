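"""Expression normalization, quartile classes, and specificity ranking.

Genes are binned into four expression classes relative to the
distribution of expression in one reference cell population:

* ``not``    — below the first quartile (q1)
* ``low``    — from q1 up to (but excluding) the mean
* ``medium`` — from the mean up to and including the third quartile (q3)
* ``high``   — above q3

The bands are applied in that order, so they are exhaustive and mutually
exclusive even on skewed distributions where the mean exceeds q3 (the
medium band is then empty) or falls below q1 (empty low band). Quantiles
use linear interpolation between order statistics.

Candidate genes are ranked by how specific their expression is to a
target cell type. The default specificity score is a pseudocounted
log-ratio against the strongest competing cell type:

    score(g) = log2( (v_target(g) + 1) / (max_{c != target} v_c(g) + 1) )

so score 0 means the target ties its best competitor, positive scores
mean target-enriched expression. Alternatives (ratio against the mean of
the other cell types, or a z-score across cell types) are provided for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EXPRESSION_CLASSES",
    "ClassThresholds",
    "cpm",
    "classify_expression",
    "specificity_scores",
    "specificity_rank",
]

EXPRESSION_CLASSES = ("not", "low", "medium", "high")


@dataclass(frozen=True)
class ClassThresholds:
    """Quartile/mean cut points of the reference expression column."""

    q1: float
    mean: float
    q3: float

    def __post_init__(self) -> None:
        if self.q1 > self.q3:
            raise ValueError("q1 must not exceed q3")

    def classify(self, value: float) -> str:
        if value < self.q1:
            return "not"
        if value < self.mean:
            return "low"
        if value <= self.q3:
            return "medium"
        return "high"


def cpm(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Counts-per-million normalization, per sample column.

    Each column is scaled by 1e6 / column-sum, so every column sums to
    exactly one million (up to floating-point error). An all-zero column
    is an error: its library size is undefined.
    """
    if isinstance(counts, pd.Series):
        total = float(counts.sum())
        if total <= 0:
            raise ValueError("library size is zero; cannot compute CPM")
        return counts / total * 1e6
    sums = counts.sum(axis=0)
    zero = [c for c in counts.columns if sums[c] <= 0]
    if zero:
        raise ValueError(f"zero library size in column(s) {zero}; cannot compute CPM")
    return counts / sums * 1e6


def classify_expression(
    values: pd.Series | np.ndarray | list[float],
) -> tuple[ClassThresholds, dict[str, str] | list[str]]:
    """Classify expression values into the four quartile classes.

    Thresholds (q1, mean, q3) are computed from the input vector itself
    with linearly interpolated quantiles. Requires >= 4 values. Returns
    the thresholds plus a gene -> class mapping when the input is an
    indexed Series, otherwise a list of classes in input order.
    """
    arr = np.asarray(values.values if isinstance(values, pd.Series) else values, dtype=float)
    if arr.size < 4:
        raise ValueError(f"need >= 4 values to form quartile classes, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError("expression values must be finite")
    thresholds = ClassThresholds(
        q1=float(np.quantile(arr, 0.25)),
        mean=float(arr.mean()),
        q3=float(np.quantile(arr, 0.75)),
    )
    classes = [thresholds.classify(v) for v in arr]
    if isinstance(values, pd.Series):
        return thresholds, dict(zip(values.index, classes))
    return thresholds, classes


def specificity_scores(
    matrix: pd.DataFrame,
    target: str,
    metric: str = "log_ratio_max",
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene specificity of expression for the target cell type.

    ``log_ratio_max`` (default): log2 ratio of the target value to the
    maximum over the other cell types, both pseudocounted.
    ``log_ratio_mean``: same against the mean of the other cell types.
    ``zscore``: (target - row mean) / row std across cell types (0 for
    constant rows).
    """
    if target not in matrix.columns:
        raise KeyError(f"target cell type {target!r} not in matrix columns")
    others = matrix.drop(columns=[target])
    if others.shape[1] == 0:
        raise ValueError("specificity needs >= 2 cell types")
    tgt = matrix[target].astype(float)
    if metric == "log_ratio_max":
        ref = others.max(axis=1).astype(float)
        return np.log2((tgt + pseudocount) / (ref + pseudocount))
    if metric == "log_ratio_mean":
        ref = others.mean(axis=1).astype(float)
        return np.log2((tgt + pseudocount) / (ref + pseudocount))
    if metric == "zscore":
        mu = matrix.mean(axis=1)
        sd = matrix.std(axis=1, ddof=0)
        out = (tgt - mu) / sd.replace(0.0, np.nan)
        return out.fillna(0.0)
    raise ValueError(f"unknown specificity metric {metric!r}")


def specificity_rank(
    matrix: pd.DataFrame,
    target: str,
    candidates: list[str] | set[str],
    metric: str = "log_ratio_max",
) -> pd.DataFrame:
    """Rank candidate genes by descending target-cell-type specificity.

    Ties are broken lexicographically by gene_id; rank 1 is the most
    specific gene. Candidates missing from the matrix raise, listing the
    missing identifiers.
    """
    cand = sorted(candidates)
    missing = [g for g in cand if g not in matrix.index]
    if missing:
        raise KeyError(f"candidate gene(s) absent from expression matrix: {missing}")
    scores = specificity_scores(matrix.loc[cand], target, metric=metric)
    if not np.isfinite(scores.values).all():
        raise ValueError("non-finite specificity scores")
    ordered = sorted(cand, key=lambda g: (-scores[g], g))
    return pd.DataFrame(
        {
            "gene_id": ordered,
            "specificity_score": [float(scores[g]) for g in ordered],
            "rank": list(range(1, len(ordered) + 1)),
        }
    ).set_index("gene_id")
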