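"""Classification performance metrics computed from prediction tables.

Fifteen metrics are supported: ``auroc``, ``accuracy``, ``balanced_accuracy``,
``brier``, ``f1``, ``fdr``, ``fnr``, ``fpr``, ``mcc``, ``mmce``, ``npv``,
``ppv``, ``recall``, ``tnr``, ``tpr``.

Binary problems use the lexicographically second class level as the positive
class unless the caller designates one.  Problems with more than two classes
are scored one-vs-rest per class (using that class's probability column for
the threshold-free metrics) and averaged with equal class weights (macro).

AUROC follows the Mann-Whitney identity: the fraction of (positive, negative)
pairs in which the positive sample receives the higher score, ties counted
as half.  Undefined metrics (single-class truth) are reported as NaN rather
than a misleading number; 0/0 ratios in confusion-derived metrics yield 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "METRIC_IDS",
    "ConfusionCounts",
    "MetricRecord",
    "confusion",
    "auroc",
    "brier",
    "derived_metrics",
    "score_predictions",
]

METRIC_IDS = (
    "accuracy",
    "auroc",
    "balanced_accuracy",
    "brier",
    "f1",
    "fdr",
    "fnr",
    "fpr",
    "mcc",
    "mmce",
    "npv",
    "ppv",
    "recall",
    "tnr",
    "tpr",
)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for a designated positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricRecord:
    """One metric value in its benchmark context (tidy-row granularity)."""

    metric: str
    value: float
    iteration: int | None = None
    algorithm_id: str | None = None
    combo_id: str | None = None
    feature_count: str = "all"


def confusion(pred: "PredictionTable", positive: str) -> ConfusionCounts:
    """One-vs-rest confusion counts of discrete predictions against truth."""
    if positive not in pred.class_levels:
        raise ValueError(f"{positive!r} is not a class level of this prediction table")
    actual = np.asarray(pred.actual_labels) == positive
    predicted = np.asarray(pred.predicted_labels) == positive
    return ConfusionCounts(
        tp=int(np.sum(actual & predicted)),
        fp=int(np.sum(~actual & predicted)),
        tn=int(np.sum(~actual & ~predicted)),
        fn=int(np.sum(actual & ~predicted)),
    )


def auroc(scores: Sequence[float], is_positive: Sequence[bool]) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity.

    Returns NaN when either class is absent from the truth.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks give ties half credit
    rank_sum = float(ranks[positive].sum())
    u_statistic = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u_statistic / (n_pos * n_neg)


def brier(prob_positive: Sequence[float], is_positive: Sequence[bool]) -> float:
    """Mean squared difference between predicted probability and 0/1 outcome."""
    probs = np.asarray(prob_positive, dtype=float)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    outcome = np.asarray(is_positive, dtype=float)
    return float(np.mean((probs - outcome) ** 2))


def _ratio(numerator: float, denominator: float) -> float:
    """0/0 -> 0 so degenerate folds still produce rectangular output."""
    return numerator / denominator if denominator != 0 else 0.0


def derived_metrics(c: ConfusionCounts) -> dict[str, float]:
    """All confusion-derived metrics for one positive class.

    Any ratio with a zero denominator is reported as 0.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    accuracy = _ratio(tp + tn, c.n)
    tpr = _ratio(tp, tp + fn)
    tnr = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    mcc_denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "accuracy": accuracy,
        "mmce": 1.0 - accuracy,
        "tpr": tpr,
        "recall": tpr,
        "tnr": tnr,
        "fpr": 1.0 - tnr,
        "fnr": 1.0 - tpr,
        "ppv": ppv,
        "npv": npv,
        "fdr": 1.0 - ppv,
        "f1": _ratio(2 * tp, 2 * tp + fp + fn),
        "balanced_accuracy": (tpr + tnr) / 2.0,
        "mcc": _ratio(tp * tn - fp * fn, mcc_denom),
    }


def _one_vs_rest(pred: "PredictionTable", positive: str) -> dict[str, float]:
    values = derived_metrics(confusion(pred, positive))
    actual = np.asarray(pred.actual_labels) == positive
    probs = pred.probabilities[positive].to_numpy()
    values["auroc"] = auroc(probs, actual)
    values["brier"] = brier(probs, actual)
    return values


def score_predictions(
    pred: "PredictionTable",
    positive: str | None = None,
    context: Mapping[str, object] | None = None,
) -> list[MetricRecord]:
    """Score one prediction table, emitting all 15 metrics as tidy records.

    Two-class problems are scored once against the designated positive class
    (default: lexicographically second level).  Problems with more classes are
    scored per class one-vs-rest and macro-averaged; a per-class AUROC that is
    undefined (class absent from the truth) is dropped from its average.
    """
    levels = pred.class_levels
    if len(levels) < 2:
        raise ValueError("prediction table must carry at least 2 class levels")
    if len(levels) == 2:
        pos = positive if positive is not None else sorted(levels)[1]
        per_metric = _one_vs_rest(pred, pos)
    else:
        per_class = [_one_vs_rest(pred, level) for level in levels]
        per_metric = {}
        for metric in METRIC_IDS:
            values = [pc[metric] for pc in per_class if not math.isnan(pc[metric])]
            per_metric[metric] = float(np.mean(values)) if values else float("nan")
    ctx = dict(context or {})
    return [
        MetricRecord(
            metric=metric,
            value=per_metric[metric],
            iteration=ctx.get("iteration"),
            algorithm_id=ctx.get("algorithm_id"),
            combo_id=ctx.get("combo_id"),
            feature_count=str(ctx.get("feature_count", "all")),
        )
        for metric in METRIC_IDS
    ]
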