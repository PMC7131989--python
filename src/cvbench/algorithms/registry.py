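"""Algorithm registry: classifiers and feature rankers behind one contract.

Every classification algorithm is registered as an adapter that builds an
estimator from a named hyperparameter combination.  Algorithms live in a
single machine-learning ecosystem (scikit-learn, plus xgboost), but the
registry is open: :func:`register_classifier` and :func:`register_ranker`
accept third-party adapters implementing the same contract.

Hyperparameter combinations are declared in YAML files shipped with the
package (one file per classification algorithm).  Each algorithm has exactly
one combination named ``default``; alternatives are either listed explicitly
or generated as the Cartesian product of a parameter grid.

The adapter contract guarantees:

* training is deterministic given (spec, data, seed);
* ``class_levels`` are the sorted distinct labels of the training partition
  and probability columns follow that order;
* probability vectors are non-negative and sum to one; adapters that natively
  emit only discrete labels are wrapped to emit one-hot vectors;
* the discrete prediction is the argmax of the probability vector, with ties
  broken toward the earlier class in ``class_levels`` order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from ..dataio import NUMERIC, Dataset

__all__ = [
    "ClassifierSpec",
    "RankerSpec",
    "TrainedModel",
    "PredictionTable",
    "RegistryError",
    "AdapterError",
    "DegenerateTrainingError",
    "register_classifier",
    "register_ranker",
    "list_algorithms",
    "hyperparam_combos",
    "default_spec",
    "train_classifier",
    "predict",
    "rank_features",
]


class RegistryError(KeyError):
    """Unknown algorithm identifier."""


class AdapterError(RuntimeError):
    """A back-end failure, wrapped with the offending algorithm's identity."""


class DegenerateTrainingError(ValueError):
    """Training partition contains fewer than 2 class levels."""


@dataclass(frozen=True)
class ClassifierSpec:
    """An algorithm identity plus one named hyperparameter combination."""

    algorithm_id: str
    combo_id: str = "default"
    params: dict = field(default_factory=dict)

    def __hash__(self) -> int:
        return hash((self.algorithm_id, self.combo_id))


@dataclass(frozen=True)
class RankerSpec:
    """A feature-ranking algorithm identity plus its parameters."""

    algorithm_id: str
    params: dict = field(default_factory=dict)

    def __hash__(self) -> int:
        return hash(self.algorithm_id)


@dataclass
class TrainedModel:
    """Fitted estimator plus the class order fixed at training time."""

    spec: ClassifierSpec
    estimator: object
    class_levels: list[str]
    feature_names: list[str]
    probabilistic: bool


@dataclass
class PredictionTable:
    """Per-sample class probabilities and discrete predictions for one cell."""

    sample_ids: list[str]
    actual_labels: list[str]
    probabilities: pd.DataFrame  # one column per class level, rows = samples
    predicted_labels: list[str]

    @property
    def class_levels(self) -> list[str]:
        return list(self.probabilities.columns)

    def __post_init__(self) -> None:
        probs = self.probabilities.to_numpy()
        if probs.size:
            if probs.min() < -1e-9 or probs.max() > 1 + 1e-9:
                raise ValueError("probabilities outside [0, 1]")
            sums = probs.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError("probability vectors must sum to 1")


@dataclass
class _ClassifierEntry:
    algorithm_id: str
    factory: Callable[[dict], object]
    combos: list[ClassifierSpec]
    probabilistic: bool = True


@dataclass
class _RankerEntry:
    algorithm_id: str
    score_fn: Callable[[np.ndarray, np.ndarray, int, dict], np.ndarray]


_CLASSIFIERS: dict[str, _ClassifierEntry] = {}
_RANKERS: dict[str, _RankerEntry] = {}


def register_classifier(
    algorithm_id: str,
    factory: Callable[[dict], object],
    combos: Sequence[ClassifierSpec],
    probabilistic: bool = True,
) -> None:
    """Register a classification adapter.

    ``factory(params)`` must return an unfitted estimator exposing ``fit`` and
    ``predict`` (and ``predict_proba`` when *probabilistic*).  The first combo
    must be named ``default``.
    """
    combos = list(combos)
    if not combos or combos[0].combo_id != "default":
        raise ValueError(f"{algorithm_id}: first combo must be 'default'")
    ids = [c.combo_id for c in combos]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{algorithm_id}: duplicate combo ids")
    _CLASSIFIERS[algorithm_id] = _ClassifierEntry(
        algorithm_id, factory, combos, probabilistic
    )


def register_ranker(algorithm_id: str, score_fn: Callable) -> None:
    """Register a feature ranker.

    ``score_fn(X, y_encoded, seed, params)`` must return one relevance score
    per column of ``X`` (higher = more informative).
    """
    _RANKERS[algorithm_id] = _RankerEntry(algorithm_id, score_fn)


def list_algorithms(kind: str = "classifier") -> list[str]:
    """Registered algorithm ids in declaration order."""
    if kind == "classifier":
        return list(_CLASSIFIERS)
    if kind == "ranker":
        return list(_RANKERS)
    raise ValueError(f"unknown algorithm kind {kind!r}")


def _get_classifier(algorithm_id: str) -> _ClassifierEntry:
    try:
        return _CLASSIFIERS[algorithm_id]
    except KeyError:
        raise RegistryError(
            f"unknown classifier {algorithm_id!r}; registered: {list(_CLASSIFIERS)}"
        ) from None


def hyperparam_combos(algorithm_id: str) -> list[ClassifierSpec]:
    """All named hyperparameter combinations; element 0 is ``default``."""
    return list(_get_classifier(algorithm_id).combos)


def default_spec(algorithm_id: str) -> ClassifierSpec:
    return _get_classifier(algorithm_id).combos[0]


def _as_matrix(d: Dataset) -> np.ndarray:
    if any(kind != NUMERIC for kind in d.feature_kinds.values()):
        raise ValueError(
            "classifier input must be fully numeric; run one-hot encoding first"
        )
    X = d.X.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("classifier input must be missing-free; run imputation first")
    return X


def _seeded(estimator: object, seed: int) -> object:
    if hasattr(estimator, "get_params") and "random_state" in estimator.get_params():
        estimator.set_params(random_state=int(seed) % (2**31))
    return estimator


def train_classifier(spec: ClassifierSpec, train: Dataset, seed: int) -> TrainedModel:
    """Fit *spec* on a numeric, missing-free training partition.

    Deterministic given (spec, train, seed).  Class order is fixed at training
    time as the sorted distinct labels of the partition.
    """
    entry = _get_classifier(spec.algorithm_id)
    X = _as_matrix(train)
    levels = sorted(train.y.astype(str).unique())
    if len(levels) < 2:
        raise DegenerateTrainingError(
            f"training partition has a single class level: {levels}"
        )
    y = np.searchsorted(np.array(levels), train.y.astype(str).to_numpy())
    try:
        estimator = _seeded(entry.factory(dict(spec.params)), seed)
        estimator.fit(X, y)
    except DegenerateTrainingError:
        raise
    except Exception as exc:
        raise AdapterError(f"{spec.algorithm_id} [{spec.combo_id}] failed: {exc}") from exc
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        class_levels=levels,
        feature_names=train.feature_names,
        probabilistic=entry.probabilistic and hasattr(estimator, "predict_proba"),
    )


def predict(model: TrainedModel, d: Dataset) -> PredictionTable:
    """Predict class probabilities and discrete labels for *d*.

    Discrete-only adapters are wrapped to emit one-hot probability vectors.
    Probabilities are clipped to [0, 1] and renormalized to guard against
    floating-point drift in the back-end.
    """
    if d.feature_names != model.feature_names:
        raise ValueError("prediction features do not match training features")
    X = _as_matrix(d)
    n_classes = len(model.class_levels)
    try:
        if model.probabilistic:
            probs = np.asarray(model.estimator.predict_proba(X), dtype=float)
        else:
            hard = np.asarray(model.estimator.predict(X), dtype=int)
            probs = np.zeros((len(hard), n_classes))
            probs[np.arange(len(hard)), hard] = 1.0
    except Exception as exc:
        raise AdapterError(f"{model.spec.algorithm_id} prediction failed: {exc}") from exc
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum(axis=1, keepdims=True)
    # argmax takes the first maximum -> ties go to the earlier class level
    predicted = [model.class_levels[i] for i in probs.argmax(axis=1)]
    return PredictionTable(
        sample_ids=d.sample_ids,
        actual_labels=list(d.y.astype(str)),
        probabilities=pd.DataFrame(probs, index=d.X.index, columns=model.class_levels),
        predicted_labels=predicted,
    )


def rank_features(spec: RankerSpec, train: Dataset, seed: int) -> list[str]:
    """Rank the features of *train*, most informative first.

    Returns a permutation of ``train.feature_names``.  Ties in relevance score
    are broken by original feature order, so the result is deterministic.
    """
    try:
        entry = _RANKERS[spec.algorithm_id]
    except KeyError:
        raise RegistryError(
            f"unknown ranker {spec.algorithm_id!r}; registered: {list(_RANKERS)}"
        ) from None
    X = _as_matrix(train)
    levels = sorted(train.y.astype(str).unique())
    if len(levels) < 2:
        raise DegenerateTrainingError(
            f"training partition has a single class level: {levels}"
        )
    y = np.searchsorted(np.array(levels), train.y.astype(str).to_numpy())
    try:
        scores = np.asarray(
            entry.score_fn(X, y, int(seed) % (2**31), dict(spec.params)), dtype=float
        )
    except DegenerateTrainingError:
        raise
    except Exception as exc:
        raise AdapterError(f"{spec.algorithm_id} ranking failed: {exc}") from exc
    if scores.shape != (train.n_features,):
        raise AdapterError(
            f"{spec.algorithm_id} returned {scores.shape} scores for "
            f"{train.n_features} features"
        )
    scores = np.nan_to_num(scores, nan=-np.inf)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [train.feature_names[i] for i in order]


def _combos_from_config(config: dict) -> list[ClassifierSpec]:
    algorithm_id = config["id"]
    default = dict(config.get("default", {}))
    combos = [ClassifierSpec(algorithm_id, "default", default)]
    for alt in config.get("combos", []):
        params = {**default, **alt["params"]}
        combos.append(ClassifierSpec(algorithm_id, alt["id"], params))
    if "grid" in config:
        keys = list(config["grid"])
        for values in itertools.product(*(config["grid"][k] for k in keys)):
            params = {**default, **dict(zip(keys, values))}
            combo_id = "|".join(f"{k}={v}" for k, v in zip(keys, values))
            if params == default:
                continue  # the default point of the grid is already element 0
            combos.append(ClassifierSpec(algorithm_id, combo_id, params))
    return combos


def load_builtin_configs() -> dict[str, dict]:
    """Parse the YAML hyperparameter files shipped with the package."""
    configs = {}
    root = resources.files(__package__) / "configs"
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            config = yaml.safe_load(entry.read_text())
            configs[config["id"]] = config
    return configs
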