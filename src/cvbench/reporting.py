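"""Borda-count rank aggregation and tidy tab-delimited output writers.

A benchmark run produces five tab-delimited files:

``predictions.tsv``
    one row per (description, iteration, algorithm, combo, sample): the
    actual label, one probability column per class level, and the discrete
    prediction.
``metrics.tsv``
    long/tidy: one row per (description, iteration, algorithm, combo,
    feature count, metric, value).
``nested.tsv``
    every option evaluated on every inner fold, with a ``chosen`` flag
    marking the option used for the outer predictions.
``feature_ranks.tsv``
    per (outer iteration, ranker): Borda totals, final ranks, and the mean
    raw rank of every feature across the inner folds.
``log.txt``
    the invocation arguments, seed, package version, per-cell wall-clock
    times, and any per-cell errors.

All data files are rectangular, header-first, and byte-reproducible under a
fixed seed; missing values are encoded as ``NA``.  The log contains wall
times and is therefore excluded from the byte-reproducibility guarantee.

Borda variant: in a ranking of F features, the feature at (1-based) position
r earns F - r points, so a last-place feature earns 0.  When every ranking
is a full permutation this ordering coincides with ordering by ascending
mean rank.  Ties in total points are broken by feature name, ascending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .crossval import BenchmarkResult

__all__ = [
    "AggregateRanking",
    "borda_aggregate",
    "write_predictions",
    "write_metrics",
    "write_nested",
    "write_feature_ranks",
    "write_log",
    "write_all",
]

NA = "NA"


class AggregationError(ValueError):
    """Rankings do not cover a common feature set."""


@dataclass(frozen=True)
class AggregateRanking:
    """Borda-aggregated feature ranking.

    ``order`` lists features best-first; ``points`` and ``mean_rank`` are
    keyed by feature name.
    """

    order: tuple[str, ...]
    points: dict[str, int]
    mean_rank: dict[str, float]

    def rank_of(self, feature: str) -> int:
        """1-based final rank of *feature*."""
        return self.order.index(feature) + 1


def borda_aggregate(rankings: Sequence[Sequence[str]]) -> AggregateRanking:
    """Aggregate full-permutation rankings by Borda count.

    Each ranking must be a permutation of the same feature set.
    """
    if not rankings:
        raise AggregationError("need at least one ranking to aggregate")
    feature_set = set(rankings[0])
    n_features = len(feature_set)
    if len(rankings[0]) != n_features:
        raise AggregationError("ranking contains duplicate features")
    points: dict[str, int] = {f: 0 for f in feature_set}
    rank_sums: dict[str, int] = {f: 0 for f in feature_set}
    for ranking in rankings:
        if set(ranking) != feature_set or len(ranking) != n_features:
            raise AggregationError("rankings cover differing feature sets")
        for position, feature in enumerate(ranking, start=1):
            points[feature] += n_features - position
            rank_sums[feature] += position
    order = tuple(sorted(feature_set, key=lambda f: (-points[f], f)))
    mean_rank = {f: rank_sums[f] / len(rankings) for f in feature_set}
    return AggregateRanking(order=order, points=points, mean_rank=mean_rank)


def _format_value(value) -> str:
    if value is None:
        return NA
    if isinstance(value, float) and math.isnan(value):
        return NA
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _write_table(frame: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        frame.to_csv(handle, sep="\t", index=False, lineterminator="\n", na_rep=NA)
    return path


def write_predictions(result: BenchmarkResult, directory: str | Path) -> Path:
    """Per-sample probabilities and discrete predictions, one row per sample."""
    rows = []
    levels = result.class_levels
    for cell in sorted(result.cells, key=lambda c: (c.iteration, c.algorithm_id, c.combo_id)):
        if cell.predictions is None:
            continue
        pred = cell.predictions
        for i, sid in enumerate(pred.sample_ids):
            row = {
                "description": result.description,
                "iteration": cell.iteration,
                "algorithm": cell.algorithm_id,
                "combo": cell.combo_id,
                "ranker": cell.ranker_id or NA,
                "sample_id": sid,
                "actual": pred.actual_labels[i],
            }
            for level in levels:
                row[f"prob_{level}"] = _format_value(float(pred.probabilities.iloc[i][level]))
            row["predicted"] = pred.predicted_labels[i]
            rows.append(row)
    columns = [
        "description", "iteration", "algorithm", "combo", "ranker",
        "sample_id", "actual", *(f"prob_{l}" for l in levels), "predicted",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return _write_table(frame, Path(directory) / "predictions.tsv")


def write_metrics(result: BenchmarkResult, directory: str | Path) -> Path:
    """Tidy long-format metrics: one metric value per row."""
    rows = []
    for cell in sorted(result.cells, key=lambda c: (c.iteration, c.algorithm_id, c.combo_id)):
        for record in cell.metrics:
            rows.append(
                {
                    "description": result.description,
                    "iteration": cell.iteration,
                    "algorithm": cell.algorithm_id,
                    "combo": cell.combo_id,
                    "ranker": cell.ranker_id or NA,
                    "feature_count": cell.feature_count,
                    "metric": record.metric,
                    "value": _format_value(record.value),
                }
            )
    columns = [
        "description", "iteration", "algorithm", "combo", "ranker",
        "feature_count", "metric", "value",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return _write_table(frame, Path(directory) / "metrics.tsv")


def write_nested(result: BenchmarkResult, directory: str | Path) -> Path:
    """Every inner-fold evaluation of every candidate option."""
    rows = []
    ordered = sorted(
        result.nested_records,
        key=lambda r: (
            r.outer_iteration, r.algorithm_id, r.ranker_id or "", r.combo_id,
            _feature_sort_key(r.feature_count), r.inner_iteration,
        ),
    )
    for record in ordered:
        for metric, value in sorted(record.metrics.items()):
            rows.append(
                {
                    "description": result.description,
                    "outer_iteration": record.outer_iteration,
                    "inner_iteration": record.inner_iteration,
                    "algorithm": record.algorithm_id,
                    "combo": record.combo_id,
                    "ranker": record.ranker_id or NA,
                    "feature_count": record.feature_count,
                    "metric": metric,
                    "value": _format_value(value),
                    "chosen": str(record.chosen),
                }
            )
    columns = [
        "description", "outer_iteration", "inner_iteration", "algorithm",
        "combo", "ranker", "feature_count", "metric", "value", "chosen",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return _write_table(frame, Path(directory) / "nested.tsv")


def _feature_sort_key(feature_count: str):
    try:
        return (0, int(feature_count))
    except ValueError:
        return (1, 0)


def write_feature_ranks(result: BenchmarkResult, directory: str | Path) -> Path:
    """Borda-aggregated feature ranks per (outer iteration, ranker)."""
    rows = []
    groups: dict[tuple[int, str], list] = {}
    for record in result.rankings:
        groups.setdefault((record.outer_iteration, record.ranker_id), []).append(
            list(record.ranking)
        )
    for (outer_iteration, ranker_id) in sorted(groups):
        aggregate = borda_aggregate(groups[(outer_iteration, ranker_id)])
        for rank, feature in enumerate(aggregate.order, start=1):
            rows.append(
                {
                    "description": result.description,
                    "outer_iteration": outer_iteration,
                    "ranker": ranker_id,
                    "feature": feature,
                    "borda_points": aggregate.points[feature],
                    "mean_rank": _format_value(aggregate.mean_rank[feature]),
                    "final_rank": rank,
                }
            )
    columns = [
        "description", "outer_iteration", "ranker", "feature",
        "borda_points", "mean_rank", "final_rank",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return _write_table(frame, Path(directory) / "feature_ranks.tsv")


def write_log(result: BenchmarkResult, directory: str | Path) -> Path:
    """Run log: arguments, seed, version, per-cell times and errors."""
    from . import __version__

    path = Path(directory) / "log.txt"
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"cvbench version: {__version__}",
        f"description: {result.description}",
        f"seed: {result.plan.seed}",
        "plan:",
    ]
    for field_name in (
        "scheme", "outer_count", "nested_count", "train_fraction",
        "feature_count_grid", "selection_metric",
    ):
        lines.append(f"  {field_name}: {getattr(result.plan, field_name)}")
    if result.arguments:
        lines.append("arguments:")
        for key, value in result.arguments.items():
            lines.append(f"  {key}: {value}")
    lines.append("cells:")
    for cell in result.cells:
        status = f"error={cell.error}" if cell.error else "ok"
        ranker = f" ranker={cell.ranker_id}" if cell.ranker_id else ""
        lines.append(
            f"  iteration={cell.iteration} algorithm={cell.algorithm_id} "
            f"combo={cell.combo_id}{ranker} features={cell.feature_count} "
            f"elapsed_seconds={cell.elapsed_seconds:.3f} {status}"
        )
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines) + "\n")
    return path


def write_all(result: BenchmarkResult, directory: str | Path) -> dict[str, Path]:
    """Write the five output files and return their paths."""
    directory = Path(directory)
    return {
        "predictions": write_predictions(result, directory),
        "metrics": write_metrics(result, directory),
        "nested": write_nested(result, directory),
        "feature_ranks": write_feature_ranks(result, directory),
        "log": write_log(result, directory),
    }
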