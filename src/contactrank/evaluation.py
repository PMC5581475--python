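"""CASP-style assessment: Top5 / L/10 / L/5 precision per range class.

Precision is TP / (TP + FP) over the k highest-scored predicted pairs,
reported as a percentage.  k is 5, floor(L/10) or floor(L/5) (clamped to at
least 1), with L the domain length.  Aggregation is macro: the arithmetic
mean of per-target precisions, never a pool of pairs across targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ASSESSED_RANGES, ContactMap, RangeClass, classify_separation
from .io_formats import PredictionList

__all__ = [
    "precision_at_k",
    "k_from_L",
    "paired_t_test",
    "scatter_report",
    "evaluate_target",
    "aggregate_report",
    "METRICS",
]

METRICS = ("top5", "L10", "L5")


def k_from_L(L: int, metric: str) -> int:
    """List depth for a metric: top5 -> 5, L10 -> floor(L/10), L5 -> floor(L/5).

    Floored depths are clamped to at least 1.
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    if metric == "top5":
        return 5
    if metric == "L10":
        return max(1, math.floor(L / 10))
    if metric == "L5":
        return max(1, math.floor(L / 5))
    raise ValueError(f"unknown metric {metric!r}")


def precision_at_k(predictions: PredictionList, cmap: ContactMap,
                   range_class: RangeClass, k: int) -> float | None:
    """Percent of true contacts among the k top-scored pairs of one range.

    Predictions outside ``range_class`` are ignored.  Pairs whose true label
    is undefined (missing coordinates) are dropped from numerator and
    denominator.  Returns None (with a warning) when no labelled prediction
    survives.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    in_range = [
        (i, j) for i, j, _ in predictions.records
        if classify_separation(i, j) is range_class
    ]
    top = in_range[:k]
    if not top:
        warnings.warn(
            f"{predictions.target_id}: no predictions in range {range_class.value}"
        )
        return None
    tp = taken = 0
    for i, j in top:
        if not cmap.defined[i - 1, j - 1]:
            continue
        taken += 1
        tp += int(cmap.contacts[i - 1, j - 1])
    if taken == 0:
        warnings.warn(
            f"{predictions.target_id}: no defined labels among top-{k} "
            f"{range_class.value}-range predictions"
        )
        return None
    return 100.0 * tp / taken


def paired_t_test(precisions_a: np.ndarray, precisions_b: np.ndarray) -> float:
    """Two-sided paired Student's t-test p-value on per-target precisions.

    Degenerate cases: all differences zero -> p = 1.0; zero variance with a
    non-zero mean difference -> p = 0.0 (t is infinite).
    """
    a = np.asarray(precisions_a, dtype=float)
    b = np.asarray(precisions_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("precision vectors must cover the same targets")
    if a.size < 2:
        raise ValueError("paired t-test needs at least two targets")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return 1.0 if np.allclose(d, 0.0) else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def scatter_report(per_target_a: dict[str, float],
                   per_target_b: dict[str, float]) -> pd.DataFrame:
    """Per-target (x, y) precision table for an A-vs-B scatter plot.

    Rows carry a ``side`` column: 'above' when B beats A (point above the
    x = y line), 'below' when A beats B, 'diagonal' on ties.  Raises when
    the target sets are disjoint.
    """
    common = sorted(set(per_target_a) & set(per_target_b))
    if not common:
        raise ValueError("methods share no targets")
    rows = []
    for t in common:
        x, y = per_target_a[t], per_target_b[t]
        side = "diagonal" if x == y else ("above" if y > x else "below")
        rows.append({"target": t, "x": x, "y": y, "side": side})
    return pd.DataFrame(rows)


@dataclass
class TargetEvaluation:
    target_id: str
    L: int
    cells: dict[tuple[str, str], float | None]  # (range, metric) -> percent


def evaluate_target(predictions_by_range: dict[RangeClass, PredictionList],
                    cmap: ContactMap, L: int) -> TargetEvaluation:
    """All 3 ranges x 3 metrics precision cells for one target."""
    target_id = next(iter(predictions_by_range.values())).target_id \
        if predictions_by_range else ""
    cells: dict[tuple[str, str], float | None] = {}
    for rc in ASSESSED_RANGES:
        preds = predictions_by_range.get(rc)
        for metric in METRICS:
            if preds is None:
                cells[(rc.value, metric)] = None
                continue
            k = k_from_L(L, metric)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cells[(rc.value, metric)] = precision_at_k(preds, cmap, rc, k)
    return TargetEvaluation(target_id=target_id, L=L, cells=cells)


def aggregate_report(evaluations: list[TargetEvaluation]) -> pd.DataFrame:
    """Long-format report: one row per (target, range, metric) plus MEAN rows.

    Aggregates are the arithmetic mean of per-target cells; undefined cells
    are excluded from their mean.
    """
    rows = []
    for ev in evaluations:
        for (rc, metric), val in ev.cells.items():
            rows.append({
                "target": ev.target_id, "L": ev.L, "range": rc,
                "metric": metric,
                "precision": np.nan if val is None else val,
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    means = (
        df.groupby(["range", "metric"], sort=False)["precision"]
        .mean()
        .reset_index()
    )
    means.insert(0, "target", "MEAN")
    means.insert(1, "L", 0)
    return pd.concat([df, means], ignore_index=True)
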