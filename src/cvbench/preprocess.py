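"""Leakage-safe preprocessing: imputation, one-hot encoding, robust scaling.

All parameters (medians, interquartile ranges, category levels, modes) are
estimated on a training partition and then *applied* unchanged to any other
partition, so no statistic of a validation set ever influences the transform.

Transform order at apply time is impute -> encode -> scale:

* imputation fills missing numeric cells with the training median and missing
  categorical cells with the training mode;
* one-hot encoding replaces a categorical feature with one binary indicator
  per training-observed level (named ``feature=level``); a level seen only at
  apply time yields all-zero indicators;
* robust scaling maps numeric x to (x - median) / IQR, where the IQR is the
  linear-interpolation 75th minus 25th percentile of the training column.
  A zero IQR (constant training column) degrades to centering only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CATEGORICAL, NUMERIC, Dataset

__all__ = ["PreprocessParams", "FitError", "ApplyError", "fit_preprocess", "apply_preprocess"]


class FitError(ValueError):
    """Preprocessing parameters cannot be estimated (e.g. all-missing feature)."""


class ApplyError(ValueError):
    """Dataset does not match the feature set the parameters were fitted on."""


@dataclass
class PreprocessParams:
    """Training-set statistics driving :func:`apply_preprocess`.

    ``levels`` maps each categorical feature to its training-observed levels in
    order of first appearance; ``center``/``scale`` hold the median and IQR of
    each numeric feature; ``impute_value`` holds the median (numeric) or mode
    (categorical) used to fill missing cells.
    """

    feature_kinds: dict[str, str]
    do_scale: bool
    do_impute: bool
    do_encode: bool
    levels: dict[str, list[str]] = field(default_factory=dict)
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    impute_value: dict[str, object] = field(default_factory=dict)


def _mode_first_seen(column: pd.Series):
    """Most frequent non-missing value; ties go to the earliest-seen value."""
    values = column.dropna()
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.items(), key=lambda kv: kv[1])[1]
    for v in values:
        if counts[v] == best:
            return v
    raise AssertionError("unreachable: non-empty column has a mode")


def fit_preprocess(
    train: Dataset,
    do_scale: bool = True,
    do_impute: bool = True,
    do_encode: bool = True,
) -> PreprocessParams:
    """Estimate preprocessing parameters on a training partition.

    Statistics ignore missing cells.  A feature with no observed value at all
    cannot be parameterized and raises :class:`FitError`.
    """
    if train.n_samples == 0:
        raise FitError("empty training set")
    params = PreprocessParams(
        feature_kinds=dict(train.feature_kinds),
        do_scale=do_scale,
        do_impute=do_impute,
        do_encode=do_encode,
    )
    for feat in train.feature_names:
        column = train.X[feat]
        observed = column.dropna()
        if observed.empty:
            raise FitError(f"feature {feat!r} is entirely missing in the training set")
        if train.feature_kinds[feat] == NUMERIC:
            values = observed.astype(float).to_numpy()
            q25, median, q75 = np.percentile(values, [25.0, 50.0, 75.0])
            params.center[feat] = float(median)
            params.scale[feat] = float(q75 - q25)
            params.impute_value[feat] = float(median)
        else:
            seen: list[str] = []
            for v in observed.astype(str):
                if v not in seen:
                    seen.append(v)
            params.levels[feat] = seen
            params.impute_value[feat] = str(_mode_first_seen(observed.astype(str)))
    return params


def apply_preprocess(d: Dataset, params: PreprocessParams) -> Dataset:
    """Apply fitted parameters to *d*, returning a new :class:`Dataset`.

    Never reads any statistic from *d* itself.  With imputation enabled the
    output has no missing cells; with encoding enabled it has only numeric
    features.
    """
    if set(d.feature_names) != set(params.feature_kinds):
        raise ApplyError(
            "dataset features do not match the fitted feature set: "
            f"{sorted(set(d.feature_names) ^ set(params.feature_kinds))}"
        )
    columns: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}
    order: list[str] = []
    for feat in d.feature_names:
        column = d.X[feat].copy()
        if params.do_impute:
            column = column.where(~column.isna(), params.impute_value[feat])
        if params.feature_kinds[feat] == CATEGORICAL and params.do_encode:
            as_str = column.map(lambda v: v if pd.isna(v) else str(v))
            for level in params.levels[feat]:
                name = f"{feat}={level}"
                indicator = (as_str == level).astype(float)
                # a missing cell (imputation off) stays missing in indicators
                indicator[as_str.isna()] = np.nan
                columns[name] = indicator
                kinds[name] = NUMERIC
                order.append(name)
            continue
        if params.feature_kinds[feat] == NUMERIC and params.do_scale:
            divisor = params.scale[feat] if params.scale[feat] > 0 else 1.0
            column = (column.astype(float) - params.center[feat]) / divisor
        columns[feat] = column
        kinds[feat] = params.feature_kinds[feat]
        order.append(feat)
    X = pd.DataFrame({name: columns[name] for name in order}, index=d.X.index)
    return Dataset(X=X, feature_kinds=kinds, y=d.y, name=d.name)
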