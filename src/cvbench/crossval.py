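"""Outer and nested cross-validation orchestration.

Two outer resampling schemes are supported: Monte Carlo (repeated stratified
random splits at a fixed training fraction) and stratified k-fold.  Nested
cross-validation re-applies the Monte Carlo scheme *inside* each outer
training partition to select, per algorithm, either the best hyperparameter
combination or the best number of top-ranked features, which is then used to
retrain on the full outer training partition and predict the outer
validation samples.

Leakage discipline: preprocessing parameters, feature rankings, and all
selection decisions are computed exclusively from (inner subsets of) the
training partition of the split at hand.  Outer validation samples never
enter any fitting step of their iteration.

Determinism: every random choice is driven by seeds derived from the plan
seed with ``numpy.random.SeedSequence``, keyed by iteration and algorithm,
so a whole benchmark is reproducible from (dataset, plan, seed) — and a
nested run whose search space has exactly one option reproduces the basic
run bit-for-bit.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .algorithms import (
    ClassifierSpec,
    RankerSpec,
    default_spec,
    hyperparam_combos,
    predict,
    rank_features,
    train_classifier,
)
from .algorithms.registry import PredictionTable
from .dataio import Dataset
from .metrics import MetricRecord, score_predictions
from .preprocess import apply_preprocess, fit_preprocess

__all__ = [
    "Split",
    "BenchmarkPlan",
    "NestedRecord",
    "RankingRecord",
    "CellResult",
    "BenchmarkResult",
    "StratificationError",
    "SelectionError",
    "monte_carlo_splits",
    "kfold_splits",
    "make_splits",
    "select_best_combo",
    "select_best_feature_count",
    "run_basic",
    "run_nested",
]

#: Metrics where a smaller value indicates better performance.
LOWER_IS_BETTER = frozenset({"brier", "mmce", "fdr", "fnr", "fpr"})

DEFAULT_FEATURE_COUNT_GRID = (1, 3, 5, 10, 15, 20, 50, 200)


class StratificationError(ValueError):
    """A class is too small for the requested stratified split."""


class SelectionError(RuntimeError):
    """Every candidate option failed on every inner fold."""


@dataclass(frozen=True)
class Split:
    """One train/validation partition of the sample identifiers."""

    iteration: int
    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]


@dataclass(frozen=True)
class BenchmarkPlan:
    """Everything that parameterizes a benchmark run, minus data/algorithms."""

    scheme: str = "monte_carlo"  # or "kfold"
    outer_count: int = 5
    nested_count: int = 0
    train_fraction: float = 2.0 / 3.0
    feature_count_grid: tuple[int, ...] = DEFAULT_FEATURE_COUNT_GRID
    selection_metric: str = "auroc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("monte_carlo", "kfold"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.outer_count < 1:
            raise ValueError("outer_count must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        grid = tuple(self.feature_count_grid)
        if grid and (any(c < 1 for c in grid) or list(grid) != sorted(set(grid))):
            raise ValueError("feature_count_grid must be strictly increasing, all >= 1")
        if self.selection_metric not in metrics_mod.METRIC_IDS:
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")


@dataclass(frozen=True)
class NestedRecord:
    """One inner-fold evaluation of one candidate option."""

    outer_iteration: int
    inner_iteration: int
    algorithm_id: str
    combo_id: str
    feature_count: str  # integer as text, or "all"
    ranker_id: str | None
    metrics: Mapping[str, float]
    chosen: bool = False


@dataclass(frozen=True)
class RankingRecord:
    """The feature ranking produced on one inner training partition."""

    outer_iteration: int
    inner_iteration: int
    ranker_id: str
    ranking: tuple[str, ...]


@dataclass
class CellResult:
    """Outer-level result for one (iteration, algorithm) benchmark cell."""

    iteration: int
    algorithm_id: str
    combo_id: str
    ranker_id: str | None
    feature_count: str
    predictions: PredictionTable | None
    metrics: list[MetricRecord]
    elapsed_seconds: float
    error: str | None = None


@dataclass
class BenchmarkResult:
    """Everything a benchmark produced, ready for the tidy writers."""

    description: str
    plan: BenchmarkPlan
    cells: list[CellResult] = field(default_factory=list)
    nested_records: list[NestedRecord] = field(default_factory=list)
    rankings: list[RankingRecord] = field(default_factory=list)
    class_levels: list[str] = field(default_factory=list)
    arguments: dict = field(default_factory=dict)


# --- seed derivation -------------------------------------------------------


def _algo_key(algorithm_id: str) -> int:
    return zlib.crc32(algorithm_id.encode())


def _derive_seed(base: int, *keys: int) -> int:
    state = np.random.SeedSequence([int(base), *map(int, keys)]).generate_state(1)[0]
    return int(state) % (2**31)


def _rng(base: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(base), *map(int, keys)]))


# --- splitting -------------------------------------------------------------


def _class_members(labels: pd.Series) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {}
    for sid, label in labels.astype(str).items():
        members.setdefault(label, []).append(sid)
    return members


def monte_carlo_splits(
    labels: pd.Series,
    iterations: int,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> list[Split]:
    """Repeated stratified random train/validation splits.

    The overall training size is ``round(train_fraction * n)``, allocated per
    class proportionally (largest-remainder rounding), with every class
    guaranteed at least one sample on each side.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    members = _class_members(labels)
    for level, ids in members.items():
        if len(ids) < 2:
            raise StratificationError(
                f"class {level!r} has {len(ids)} sample(s); need >= 2 to stratify"
            )
    n = len(labels)
    total_train = int(round(train_fraction * n))
    levels = sorted(members)
    quotas = {lv: train_fraction * len(members[lv]) for lv in levels}
    counts = {lv: int(np.floor(quotas[lv])) for lv in levels}
    remainder = total_train - sum(counts.values())
    by_fraction = sorted(levels, key=lambda lv: (-(quotas[lv] - counts[lv]), lv))
    for lv in by_fraction[: max(remainder, 0)]:
        counts[lv] += 1
    for lv in levels:  # both sides must see every class
        counts[lv] = min(max(counts[lv], 1), len(members[lv]) - 1)

    order = {sid: i for i, sid in enumerate(labels.index)}
    splits = []
    for it in range(iterations):
        rng = _rng(seed, 11, it)
        train: list[str] = []
        validation: list[str] = []
        for lv in levels:
            ids = list(members[lv])
            rng.shuffle(ids)
            train.extend(ids[: counts[lv]])
            validation.extend(ids[counts[lv] :])
        splits.append(
            Split(
                iteration=it,
                train_ids=tuple(sorted(train, key=order.get)),
                validation_ids=tuple(sorted(validation, key=order.get)),
            )
        )
    return splits


def kfold_splits(labels: pd.Series, k: int, seed: int = 0) -> list[Split]:
    """Stratified k-fold splits whose validation sets partition the samples.

    Within each class, members are spread as evenly as possible over the k
    folds; the folds receiving one extra member rotate across classes so the
    overall fold sizes differ by at most one.
    """
    n = len(labels)
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= {n}, got {k}")
    members = _class_members(labels)
    for level, ids in members.items():
        if len(ids) < k:
            raise StratificationError(
                f"class {level!r} has {len(ids)} sample(s); need >= k={k} to stratify"
            )
    rng = _rng(seed, 13)
    folds: list[list[str]] = [[] for _ in range(k)]
    offset = 0
    for level in sorted(members):
        ids = list(members[level])
        rng.shuffle(ids)
        base, extra = divmod(len(ids), k)
        position = 0
        for i in range(k):
            fold = (offset + i) % k
            take = base + (1 if i < extra else 0)
            folds[fold].extend(ids[position : position + take])
            position += take
        offset = (offset + extra) % k
    order = {sid: i for i, sid in enumerate(labels.index)}
    all_ids = set(labels.index)
    splits = []
    for it in range(k):
        validation = sorted(folds[it], key=order.get)
        train = sorted(all_ids - set(validation), key=order.get)
        splits.append(
            Split(iteration=it, train_ids=tuple(train), validation_ids=tuple(validation))
        )
    return splits


def make_splits(labels: pd.Series, plan: BenchmarkPlan) -> list[Split]:
    if plan.scheme == "kfold":
        return kfold_splits(labels, plan.outer_count, plan.seed)
    return monte_carlo_splits(labels, plan.outer_count, plan.train_fraction, plan.seed)


# --- selection metric handling --------------------------------------------


def _metric_value(records: Sequence[MetricRecord], metric: str) -> float:
    for record in records:
        if record.metric == metric:
            return record.value
    return float("nan")


def _mean_score(values: Sequence[float]) -> float:
    values = [v for v in values if not np.isnan(v)]
    return float(np.mean(values)) if values else float("nan")


def _better(candidate: float, incumbent: float, metric: str) -> bool:
    if np.isnan(candidate):
        return False
    if np.isnan(incumbent):
        return True
    if metric in LOWER_IS_BETTER:
        return candidate < incumbent
    return candidate > incumbent


def _metrics_dict(pred: PredictionTable) -> dict[str, float]:
    return {r.metric: r.value for r in score_predictions(pred)}


# --- nested selection ------------------------------------------------------


def _nested_splits(train: Dataset, plan: BenchmarkPlan, outer_iteration: int) -> list[Split]:
    nested_seed = _derive_seed(plan.seed, 23, outer_iteration)
    return monte_carlo_splits(
        train.y, plan.nested_count, plan.train_fraction, seed=nested_seed
    )


def select_best_combo(
    train: Dataset,
    algorithm_id: str,
    combos: Sequence[ClassifierSpec],
    plan: BenchmarkPlan,
    outer_iteration: int = 0,
    do_scale: bool = True,
    do_impute: bool = True,
    do_encode: bool = True,
) -> tuple[ClassifierSpec, list[NestedRecord]]:
    """Choose the best hyperparameter combination by nested cross-validation.

    Every combo is scored on every inner validation set; the combo with the
    best mean selection metric wins, ties going to the earlier combo in
    registry order (so the default wins ties against alternatives).
    """
    if plan.nested_count < 1:
        raise ValueError("nested selection requires plan.nested_count >= 1")
    if not combos:
        raise ValueError("need at least one hyperparameter combination")
    splits = _nested_splits(train, plan, outer_iteration)
    records: list[NestedRecord] = []
    scores: dict[str, list[float]] = {c.combo_id: [] for c in combos}
    for split in splits:
        inner_train = train.subset(split.train_ids)
        inner_val = train.subset(split.validation_ids)
        params = fit_preprocess(inner_train, do_scale, do_impute, do_encode)
        inner_train_p = apply_preprocess(inner_train, params)
        inner_val_p = apply_preprocess(inner_val, params)
        inner_seed = _derive_seed(plan.seed, 29, outer_iteration, split.iteration, _algo_key(algorithm_id))
        for combo in combos:
            try:
                model = train_classifier(combo, inner_train_p, inner_seed)
                values = _metrics_dict(predict(model, inner_val_p))
            except Exception:
                continue  # per-cell failure: skip this combo on this fold
            scores[combo.combo_id].append(values[plan.selection_metric])
            records.append(
                NestedRecord(
                    outer_iteration=outer_iteration,
                    inner_iteration=split.iteration,
                    algorithm_id=algorithm_id,
                    combo_id=combo.combo_id,
                    feature_count="all",
                    ranker_id=None,
                    metrics=values,
                )
            )
    chosen: ClassifierSpec | None = None
    best = float("nan")
    for combo in combos:  # registry order; strict improvement required
        if not scores[combo.combo_id]:
            continue
        mean = _mean_score(scores[combo.combo_id])
        if chosen is None or _better(mean, best, plan.selection_metric):
            chosen, best = combo, mean
    if chosen is None:
        raise SelectionError(
            f"all hyperparameter combinations of {algorithm_id} failed on all inner folds"
        )
    records = [
        replace(r, chosen=(r.combo_id == chosen.combo_id)) for r in records
    ]
    return chosen, records


def effective_feature_grid(grid: Sequence[int], n_features: int) -> list[int]:
    """Grid values applicable to a dataset with *n_features* encoded features.

    Values exceeding the feature count are dropped; if that empties the grid,
    the full feature count itself is used.
    """
    effective = sorted({int(c) for c in grid if int(c) <= n_features})
    return effective if effective else [int(n_features)]


def select_best_feature_count(
    train: Dataset,
    ranker: RankerSpec,
    classifier: ClassifierSpec,
    plan: BenchmarkPlan,
    outer_iteration: int = 0,
    do_scale: bool = True,
    do_impute: bool = True,
    do_encode: bool = True,
) -> tuple[int, list[RankingRecord], list[NestedRecord]]:
    """Choose how many top-ranked features to use, by nested cross-validation.

    On each inner split the ranker orders the (preprocessed) features of the
    inner training partition; the classifier is then trained on the top *c*
    features for every count in the effective grid and scored on the inner
    validation partition.  The count with the best mean selection metric is
    chosen, ties going to the smaller count (parsimony).
    """
    if plan.nested_count < 1:
        raise ValueError("nested selection requires plan.nested_count >= 1")
    if not plan.feature_count_grid:
        raise ValueError("feature_count_grid must be non-empty")
    splits = _nested_splits(train, plan, outer_iteration)
    outer_params = fit_preprocess(train, do_scale, do_impute, do_encode)
    n_encoded = apply_preprocess(train, outer_params).n_features
    grid = effective_feature_grid(plan.feature_count_grid, n_encoded)

    records: list[NestedRecord] = []
    rankings: list[RankingRecord] = []
    scores: dict[int, list[float]] = {c: [] for c in grid}
    for split in splits:
        inner_train = train.subset(split.train_ids)
        inner_val = train.subset(split.validation_ids)
        params = fit_preprocess(inner_train, do_scale, do_impute, do_encode)
        inner_train_p = apply_preprocess(inner_train, params)
        inner_val_p = apply_preprocess(inner_val, params)
        seed_keys = (outer_iteration, split.iteration, _algo_key(ranker.algorithm_id))
        ranking = rank_features(ranker, inner_train_p, _derive_seed(plan.seed, 31, *seed_keys))
        rankings.append(
            RankingRecord(
                outer_iteration=outer_iteration,
                inner_iteration=split.iteration,
                ranker_id=ranker.algorithm_id,
                ranking=tuple(ranking),
            )
        )
        inner_seed = _derive_seed(
            plan.seed, 29, outer_iteration, split.iteration, _algo_key(classifier.algorithm_id)
        )
        for count in grid:
            top = ranking[: min(count, len(ranking))]
            try:
                model = train_classifier(classifier, inner_train_p.subset(split.train_ids, top), inner_seed)
                values = _metrics_dict(predict(model, inner_val_p.subset(split.validation_ids, top)))
            except Exception:
                continue
            scores[count].append(values[plan.selection_metric])
            records.append(
                NestedRecord(
                    outer_iteration=outer_iteration,
                    inner_iteration=split.iteration,
                    algorithm_id=classifier.algorithm_id,
                    combo_id=classifier.combo_id,
                    feature_count=str(count),
                    ranker_id=ranker.algorithm_id,
                    metrics=values,
                )
            )
    chosen: int | None = None
    best = float("nan")
    for count in grid:  # ascending; strict improvement -> smaller count wins ties
        if not scores[count]:
            continue
        mean = _mean_score(scores[count])
        if chosen is None or _better(mean, best, plan.selection_metric):
            chosen, best = count, mean
    if chosen is None:
        raise SelectionError(
            f"feature-count search for {classifier.algorithm_id} with "
            f"{ranker.algorithm_id} failed on all inner folds"
        )
    records = [
        replace(r, chosen=(r.feature_count == str(chosen))) for r in records
    ]
    return chosen, rankings, records


# --- outer orchestration ---------------------------------------------------


def _score_cell(
    pred: PredictionTable,
    iteration: int,
    algorithm_id: str,
    combo_id: str,
    feature_count: str,
) -> list[MetricRecord]:
    return score_predictions(
        pred,
        context={
            "iteration": iteration,
            "algorithm_id": algorithm_id,
            "combo_id": combo_id,
            "feature_count": feature_count,
        },
    )


def run_basic(
    d: Dataset,
    classifiers: Sequence[ClassifierSpec],
    plan: BenchmarkPlan,
    do_scale: bool = True,
    do_impute: bool = True,
    do_encode: bool = True,
    description: str = "benchmark",
) -> BenchmarkResult:
    """Non-nested benchmark: each classifier on each outer split.

    Per cell: preprocessing is fitted on the training partition, the model is
    trained and scored on the validation partition, and wall time recorded.
    A failing cell is logged in its result and does not abort the run.
    """
    if plan.nested_count != 0:
        raise ValueError("run_basic requires plan.nested_count == 0")
    result = BenchmarkResult(
        description=description, plan=plan, class_levels=sorted(d.y.astype(str).unique())
    )
    for split in make_splits(d.y, plan):
        train = d.subset(split.train_ids)
        validation = d.subset(split.validation_ids)
        params = fit_preprocess(train, do_scale, do_impute, do_encode)
        train_p = apply_preprocess(train, params)
        validation_p = apply_preprocess(validation, params)
        for spec in classifiers:
            started = time.perf_counter()
            seed = _derive_seed(plan.seed, 17, split.iteration, _algo_key(spec.algorithm_id))
            try:
                model = train_classifier(spec, train_p, seed)
                pred = predict(model, validation_p)
                cell_metrics = _score_cell(
                    pred, split.iteration, spec.algorithm_id, spec.combo_id, "all"
                )
                error = None
            except Exception as exc:
                pred, cell_metrics, error = None, [], f"{type(exc).__name__}: {exc}"
            result.cells.append(
                CellResult(
                    iteration=split.iteration,
                    algorithm_id=spec.algorithm_id,
                    combo_id=spec.combo_id,
                    ranker_id=None,
                    feature_count="all",
                    predictions=pred,
                    metrics=cell_metrics,
                    elapsed_seconds=time.perf_counter() - started,
                    error=error,
                )
            )
    return result


def run_nested(
    d: Dataset,
    algorithms: Sequence[str],
    plan: BenchmarkPlan,
    rankers: Sequence[RankerSpec] | None = None,
    combos_by_algorithm: Mapping[str, Sequence[ClassifierSpec]] | None = None,
    do_scale: bool = True,
    do_impute: bool = True,
    do_encode: bool = True,
    description: str = "benchmark",
) -> BenchmarkResult:
    """Nested benchmark: per-algorithm option selection inside each outer split.

    Without rankers, the selectable options are each algorithm's registered
    hyperparameter combinations.  With rankers, each (ranker, algorithm) pair
    is a benchmark cell, the algorithm runs at its default hyperparameters,
    and the selectable option is the number of top-ranked features.  The
    chosen option is retrained on the full outer training partition and
    scored on the outer validation partition.
    """
    if plan.nested_count < 1:
        raise ValueError("run_nested requires plan.nested_count >= 1")
    result = BenchmarkResult(
        description=description, plan=plan, class_levels=sorted(d.y.astype(str).unique())
    )
    flags = dict(do_scale=do_scale, do_impute=do_impute, do_encode=do_encode)
    for split in make_splits(d.y, plan):
        train = d.subset(split.train_ids)
        validation = d.subset(split.validation_ids)
        params = fit_preprocess(train, do_scale, do_impute, do_encode)
        train_p = apply_preprocess(train, params)
        validation_p = apply_preprocess(validation, params)
        for algorithm_id in algorithms:
            cells = _nested_cells_for_algorithm(
                d, train, train_p, validation_p, split, algorithm_id, plan,
                rankers, combos_by_algorithm, flags, result,
            )
            result.cells.extend(cells)
    return result


def _nested_cells_for_algorithm(
    d: Dataset,
    train: Dataset,
    train_p: Dataset,
    validation_p: Dataset,
    split: Split,
    algorithm_id: str,
    plan: BenchmarkPlan,
    rankers: Sequence[RankerSpec] | None,
    combos_by_algorithm: Mapping[str, Sequence[ClassifierSpec]] | None,
    flags: dict,
    result: BenchmarkResult,
) -> list[CellResult]:
    cells: list[CellResult] = []
    outer_seed = _derive_seed(plan.seed, 17, split.iteration, _algo_key(algorithm_id))
    if not rankers:
        if combos_by_algorithm and algorithm_id in combos_by_algorithm:
            combos = list(combos_by_algorithm[algorithm_id])
        else:
            combos = hyperparam_combos(algorithm_id)
        started = time.perf_counter()
        try:
            chosen, nested = select_best_combo(
                train, algorithm_id, combos, plan, split.iteration, **flags
            )
            result.nested_records.extend(nested)
            model = train_classifier(chosen, train_p, outer_seed)
            pred = predict(model, validation_p)
            cell_metrics = _score_cell(
                pred, split.iteration, algorithm_id, chosen.combo_id, "all"
            )
            cells.append(
                CellResult(
                    iteration=split.iteration,
                    algorithm_id=algorithm_id,
                    combo_id=chosen.combo_id,
                    ranker_id=None,
                    feature_count="all",
                    predictions=pred,
                    metrics=cell_metrics,
                    elapsed_seconds=time.perf_counter() - started,
                )
            )
        except Exception as exc:
            cells.append(
                CellResult(
                    iteration=split.iteration,
                    algorithm_id=algorithm_id,
                    combo_id="default",
                    ranker_id=None,
                    feature_count="all",
                    predictions=None,
                    metrics=[],
                    elapsed_seconds=time.perf_counter() - started,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
        return cells

    classifier = default_spec(algorithm_id)
    for ranker in rankers:
        started = time.perf_counter()
        try:
            count, rankings, nested = select_best_feature_count(
                train, ranker, classifier, plan, split.iteration, **flags
            )
            result.rankings.extend(rankings)
            result.nested_records.extend(nested)
            outer_ranking = rank_features(
                ranker,
                train_p,
                _derive_seed(plan.seed, 31, split.iteration, plan.nested_count, _algo_key(ranker.algorithm_id)),
            )
            top = outer_ranking[: min(count, len(outer_ranking))]
            model = train_classifier(classifier, train_p.subset(train_p.sample_ids, top), outer_seed)
            pred = predict(model, validation_p.subset(validation_p.sample_ids, top))
            cell_metrics = _score_cell(
                pred, split.iteration, algorithm_id, classifier.combo_id, str(count)
            )
            cells.append(
                CellResult(
                    iteration=split.iteration,
                    algorithm_id=algorithm_id,
                    combo_id=classifier.combo_id,
                    ranker_id=ranker.algorithm_id,
                    feature_count=str(count),
                    predictions=pred,
                    metrics=cell_metrics,
                    elapsed_seconds=time.perf_counter() - started,
                )
            )
        except Exception as exc:
            cells.append(
                CellResult(
                    iteration=split.iteration,
                    algorithm_id=algorithm_id,
                    combo_id=classifier.combo_id,
                    ranker_id=ranker.algorithm_id,
                    feature_count="all",
                    predictions=None,
                    metrics=[],
                    elapsed_seconds=time.perf_counter() - started,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return cells
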