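"""Simulated fixture datasets: a signal-free null and planted-signal variants.

The null dataset emulates a sanity-check scenario for any benchmarking
pipeline: 500 samples with 20 standard-normal numeric features and 10
categorical features, and binary class labels drawn independently of every
feature.  Any correctly implemented, leakage-free pipeline must score at
chance (AUROC near 0.5) on such data; scoring above chance indicates
information leaking from validation samples into training.

The signal variant plants a mean shift (in units of the feature's standard
deviation) between the two classes in a chosen number of numeric features,
supporting recovery tests for feature rankers and for feature-subset-size
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import CATEGORICAL, NUMERIC, Dataset

__all__ = ["NullSpec", "SignalSpec", "generate_null", "generate_signal"]


@dataclass(frozen=True)
class NullSpec:
    """Parameters of the signal-free simulation."""

    n_samples: int = 500
    n_numeric: int = 20
    n_categorical: int = 10
    n_levels: int = 3
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_numeric < 0 or self.n_categorical < 0:
            raise ValueError("invalid simulation dimensions")
        if self.n_levels < 2:
            raise ValueError("categorical features need >= 2 levels")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie strictly between 0 and 1")


@dataclass(frozen=True)
class SignalSpec(NullSpec):
    """Null simulation plus planted class signal in some numeric features."""

    informative_features: int = 3
    effect_size: float = 2.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0 <= self.informative_features <= self.n_numeric:
            raise ValueError("informative_features must lie in [0, n_numeric]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


def _simulate(spec: NullSpec, informative: int, effect_size: float) -> tuple[Dataset, list[str]]:
    rng = np.random.default_rng(spec.seed)
    sample_ids = [f"sample_{i + 1}" for i in range(spec.n_samples)]
    labels = np.where(rng.random(spec.n_samples) < spec.class_balance, "case", "control")
    # the simulated cohort must actually contain both classes
    if len(np.unique(labels)) < 2:
        labels[0] = "case" if labels[1] == "control" else "control"

    columns: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    informative_names: list[str] = []
    for j in range(spec.n_numeric):
        name = f"num_{j + 1}"
        values = rng.normal(0.0, 1.0, spec.n_samples)
        if j < informative:
            values = values + np.where(labels == "case", effect_size, 0.0)
            informative_names.append(name)
        columns[name] = values
        kinds[name] = NUMERIC
    level_names = [f"level_{l + 1}" for l in range(spec.n_levels)]
    for j in range(spec.n_categorical):
        name = f"cat_{j + 1}"
        columns[name] = rng.choice(level_names, spec.n_samples)
        kinds[name] = CATEGORICAL

    X = pd.DataFrame(columns, index=pd.Index(sample_ids, name="id"))
    y = pd.Series(labels, index=X.index, name="Class")
    return Dataset(X=X, feature_kinds=kinds, y=y, name="simulated"), informative_names


def generate_null(spec: NullSpec = NullSpec()) -> Dataset:
    """Simulate a dataset whose labels are independent of every feature.

    Numeric features are standard normal; categorical features are uniform
    over their levels; binary labels follow ``class_balance``.  Deterministic
    for a given ``spec.seed``.
    """
    dataset, _ = _simulate(spec, informative=0, effect_size=0.0)
    return dataset


def generate_signal(spec: SignalSpec = SignalSpec()) -> tuple[Dataset, list[str]]:
    """Simulate a dataset with a planted mean shift in some numeric features.

    The first ``informative_features`` numeric columns have class-conditional
    means 0 (control) and ``effect_size`` (case); everything else matches the
    null simulation.  Returns the dataset and the ground-truth names of the
    informative features.
    """
    return _simulate(spec, spec.informative_features, spec.effect_size)
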