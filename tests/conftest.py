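import numpy as np
import pandas as pd
import pytest

from cvbench.dataio import CATEGORICAL, NUMERIC, Dataset


def random_dataset(
    rng: np.random.Generator,
    n_samples: int = 8,
    n_numeric: int = 3,
    n_categorical: int = 2,
    missing_rate: float = 0.0,
    n_classes: int = 2,
) -> Dataset:
    """Small random mixed-type dataset for I/O and plumbing tests.

    Categorical values are deliberately non-numeric strings so that feature
    kinds survive re-inference on delimited round-trips.
    """
    sample_ids = [f"s{i}" for i in range(n_samples)]
    columns, kinds = {}, {}
    for j in range(n_numeric):
        name = f"n{j}"
        values = np.round(rng.normal(size=n_samples), 4)
        columns[name] = values.astype(object)
        kinds[name] = NUMERIC
    for j in range(n_categorical):
        name = f"c{j}"
        columns[name] = rng.choice(["red", "green", "blue"], n_samples).astype(object)
        kinds[name] = CATEGORICAL
    X = pd.DataFrame(columns, index=sample_ids)
    if missing_rate > 0:
        mask = rng.random(X.shape) < missing_rate
        X = X.mask(pd.DataFrame(mask, index=X.index, columns=X.columns))
    labels = rng.choice([f"class{k}" for k in range(n_classes)], n_samples)
    labels[: n_classes] = [f"class{k}" for k in range(n_classes)]  # ensure all levels
    y = pd.Series(labels, index=X.index)
    return Dataset(X=X, feature_kinds=kinds, y=y)


def separable_dataset(n_per_class: int = 20, n_noise: int = 3, seed: int = 0) -> Dataset:
    """Two linearly separable classes: one feature fully determines the label."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    sample_ids = [f"s{i}" for i in range(n)]
    labels = np.array(["neg"] * n_per_class + ["pos"] * n_per_class)
    signal = np.where(labels == "pos", 5.0, -5.0) + rng.normal(0, 0.1, n)
    columns = {"signal": signal}
    for j in range(n_noise):
        columns[f"noise{j}"] = rng.normal(size=n)
    X = pd.DataFrame(columns, index=sample_ids)
    y = pd.Series(labels, index=X.index)
    return Dataset(X=X, feature_kinds={c: NUMERIC for c in X.columns}, y=y)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def separable():
    return separable_dataset()
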