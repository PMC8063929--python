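"""Correlation-weight feature ranking.

Each feature column is scored by the absolute Pearson correlation with
the binary class label (the point-biserial correlation); columns are
ranked by descending weight and the top k retained.  The weight is
computed on training rows only — callers are responsible for passing
training data, and the nested-CV driver does so per outer fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureRanking", "weight_correlation", "rank_and_select", "ranking_table"]


@dataclass
class FeatureRanking:
    """Weights and the descending-weight column order; top-k selection."""

    weights: np.ndarray  # (n_columns,), nonnegative
    order: np.ndarray  # permutation of column indices, descending weight
    k_selected: int
    selected: np.ndarray  # order[:k_selected]
    selected_labels: Optional[list] = None


def weight_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson r| between a feature column and a 0/1 label vector.

    The label vector may hold any two distinct values.  A constant feature
    has weight 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matched feature/label vectors of length >= 2")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes in labels, got {classes.size}")
    y01 = (y == classes[1]).astype(float)
    xc = x - x.mean()
    yc = y01 - y01.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(abs(np.sum(xc * yc) / (sx * sy)))


def rank_and_select(
    table: np.ndarray | pd.DataFrame,
    labels: Sequence,
    k: int,
    columns: Optional[Sequence] = None,
    weight_fn: Callable[[np.ndarray, np.ndarray], float] = weight_correlation,
) -> FeatureRanking:
    """Score every column, sort by descending weight, keep the top k.

    Ties are broken by ascending column index for determinism.  ``columns``
    (or the DataFrame's columns) provides human-readable labels for the
    selected features.
    """
    if isinstance(table, pd.DataFrame):
        if columns is None:
            columns = list(table.columns)
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
    y = np.asarray(labels)
    n_cols = X.shape[1]
    if not 1 <= k <= n_cols:
        raise ValueError(f"k must be in [1, {n_cols}], got {k}")
    weights = np.array([weight_fn(X[:, j], y) for j in range(n_cols)])
    # stable sort on -weight => ties resolve to the lower column index
    order = np.argsort(-weights, kind="stable")
    selected = order[:k]
    sel_labels = [columns[j] for j in selected] if columns is not None else None
    return FeatureRanking(
        weights=weights,
        order=order,
        k_selected=k,
        selected=selected,
        selected_labels=sel_labels,
    )


def ranking_table(ranking: FeatureRanking) -> pd.DataFrame:
    """Human-readable ranked-importance table (rank, weight, feature labels).

    When column labels are (condition, imf, feature) triples — or their
    "cond|imfN|feat" string encoding — they are split into the familiar
    Stimulus / IMF# / Feature columns.
    """
    rows = []
    for rank, j in enumerate(ranking.order[: ranking.k_selected], start=1):
        label = (
            ranking.selected_labels[rank - 1]
            if ranking.selected_labels is not None
            else j
        )
        row = {"rank": rank, "column": int(j), "weight": float(ranking.weights[j])}
        triple = None
        if isinstance(label, tuple) and len(label) == 3:
            triple = label
        elif isinstance(label, str) and label.count("|") == 2:
            cond, imf, feat = label.split("|")
            triple = (cond, imf, feat)
        if triple is not None:
            cond, imf, feat = triple
            row.update(
                {
                    "feature": str(feat),
                    "imf": str(imf) if not isinstance(imf, int) else f"imf{imf}",
                    "stimulus": str(cond),
                }
            )
        else:
            row["feature"] = str(label)
        rows.append(row)
    return pd.DataFrame(rows)
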