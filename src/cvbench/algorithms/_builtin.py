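"""Built-in classification and feature-ranking adapters.

Classifiers span the methodological families a benchmark should cover:
linear models, kernel methods, tree-based and ensemble approaches, Bayesian
and distance-based methods, and neural networks.  Rankers cover univariate
statistics (ANOVA F, Kruskal-Wallis, correlation, mutual information),
model-based importances, sparse-linear weights, and recursive feature
elimination.

All adapters delegate the learning itself to scikit-learn or xgboost; this
module only maps the registry contract onto each back-end's interface.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import RFE, f_classif, mutual_info_classif
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .registry import load_builtin_configs, register_classifier, register_ranker, _combos_from_config

# --- classifier factories --------------------------------------------------


def _logistic_regression(params):
    return LogisticRegression(solver="liblinear", **params)


def _svm(params):
    return SVC(probability=True, **params)


def _decision_tree(params):
    return DecisionTreeClassifier(**params)


def _random_forest(params):
    return RandomForestClassifier(**params)


def _extra_trees(params):
    return ExtraTreesClassifier(**params)


def _gradient_boosting(params):
    return GradientBoostingClassifier(**params)


def _knn(params):
    return KNeighborsClassifier(**params)


def _gaussian_nb(params):
    return GaussianNB(**params)


def _mlp(params):
    params = dict(params)
    if "hidden_layer_sizes" in params:
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
    return MLPClassifier(**params)


def _sgd(params):
    return SGDClassifier(loss="log_loss", **params)


def _nearest_centroid(params):
    # emits discrete labels only; the registry wraps predictions one-hot
    return NearestCentroid(**params)


def _xgboost(params):
    from xgboost import XGBClassifier

    return XGBClassifier(n_jobs=1, verbosity=0, eval_metric="logloss", **params)


_CLASSIFIER_FACTORIES = {
    "sklearn/logistic_regression": (_logistic_regression, True),
    "sklearn/svm": (_svm, True),
    "sklearn/decision_tree": (_decision_tree, True),
    "sklearn/random_forest": (_random_forest, True),
    "sklearn/extra_trees": (_extra_trees, True),
    "sklearn/gradient_boosting": (_gradient_boosting, True),
    "sklearn/knn": (_knn, True),
    "sklearn/gaussian_nb": (_gaussian_nb, True),
    "sklearn/mlp": (_mlp, True),
    "sklearn/sgd": (_sgd, True),
    "sklearn/nearest_centroid": (_nearest_centroid, False),
    "xgboost/xgboost": (_xgboost, True),
}

# --- ranker score functions ------------------------------------------------
# contract: score_fn(X, y_encoded, seed, params) -> one score per column,
# higher = more informative; NaN scores sort last.


def _anova_scores(X, y, seed, params):
    scores, _ = f_classif(X, y)
    return scores


def _mutual_info_scores(X, y, seed, params):
    return mutual_info_classif(X, y, random_state=seed, **params)


def _kruskal_scores(X, y, seed, params):
    groups = [y == g for g in np.unique(y)]
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        samples = [X[g, j] for g in groups]
        try:
            scores[j], _ = stats.kruskal(*samples)
        except ValueError:  # all values identical -> no discriminative power
            scores[j] = 0.0
    return scores


def _correlation_scores(X, y, seed, params):
    """Max absolute Pearson correlation with any one-vs-rest class indicator."""
    scores = np.zeros(X.shape[1])
    for level in np.unique(y):
        indicator = (y == level).astype(float)
        centered = indicator - indicator.mean()
        Xc = X - X.mean(axis=0)
        denom = np.sqrt((Xc**2).sum(axis=0) * (centered**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(Xc.T @ centered) / denom
        scores = np.fmax(scores, np.nan_to_num(r))
    return scores


def _rf_importance_scores(X, y, seed, params):
    model = RandomForestClassifier(
        n_estimators=int(params.get("n_estimators", 100)), random_state=seed
    )
    return model.fit(X, y).feature_importances_


def _extra_trees_importance_scores(X, y, seed, params):
    model = ExtraTreesClassifier(
        n_estimators=int(params.get("n_estimators", 100)), random_state=seed
    )
    return model.fit(X, y).feature_importances_


def _decision_tree_importance_scores(X, y, seed, params):
    return DecisionTreeClassifier(random_state=seed).fit(X, y).feature_importances_


def _logistic_l1_scores(X, y, seed, params):
    model = LogisticRegression(
        l1_ratio=1, solver="liblinear", C=float(params.get("C", 1.0)), random_state=seed
    )
    return np.abs(model.fit(X, y).coef_).max(axis=0)


def _rfe_scores(estimator, X, y, params):
    selector = RFE(
        estimator, n_features_to_select=1, step=float(params.get("step", 0.2))
    )
    # RFE ranking_ is 1 for the best feature; negate to make higher = better
    return -selector.fit(X, y).ranking_.astype(float)


def _rf_rfe_scores(X, y, seed, params):
    return _rfe_scores(
        RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 50)), random_state=seed
        ),
        X,
        y,
        params,
    )


def _svm_rfe_scores(X, y, seed, params):
    return _rfe_scores(
        LinearSVC(dual=False, C=float(params.get("C", 1.0)), random_state=seed),
        X,
        y,
        params,
    )


_RANKER_SCORE_FNS = {
    "sklearn/anova": _anova_scores,
    "sklearn/mutual_info": _mutual_info_scores,
    "scipy/kruskal": _kruskal_scores,
    "sklearn/correlation": _correlation_scores,
    "sklearn/random_forest_importance": _rf_importance_scores,
    "sklearn/extra_trees_importance": _extra_trees_importance_scores,
    "sklearn/decision_tree_importance": _decision_tree_importance_scores,
    "sklearn/logistic_l1": _logistic_l1_scores,
    "sklearn/random_forest_rfe": _rf_rfe_scores,
    "sklearn/svm_rfe": _svm_rfe_scores,
}


def register_builtins() -> None:
    """Register every built-in adapter (idempotent, declaration order fixed)."""
    configs = load_builtin_configs()
    for algorithm_id, (factory, probabilistic) in _CLASSIFIER_FACTORIES.items():
        if algorithm_id not in configs:
            raise RuntimeError(f"missing hyperparameter config for {algorithm_id}")
        register_classifier(
            algorithm_id,
            factory,
            _combos_from_config(configs[algorithm_id]),
            probabilistic=probabilistic,
        )
    for algorithm_id, score_fn in _RANKER_SCORE_FNS.items():
        register_ranker(algorithm_id, score_fn)
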