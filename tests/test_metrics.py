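import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cvbench.algorithms.registry import PredictionTable
from cvbench.metrics import (
    METRIC_IDS,
    ConfusionCounts,
    auroc,
    brier,
    confusion,
    derived_metrics,
    score_predictions,
)


def brute_force_auroc(scores, is_positive):
    """Independent pairwise oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    positives = [s for s, p in zip(scores, is_positive) if p]
    negatives = [s for s, p in zip(scores, is_positive) if not p]
    total = 0.0
    for sp, sn in itertools.product(positives, negatives):
        total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(positives) * len(negatives))


def table_from(actual, probs_pos, levels=("neg", "pos")):
    probs = pd.DataFrame(
        {levels[0]: 1 - np.asarray(probs_pos), levels[1]: probs_pos},
        index=[f"s{i}" for i in range(len(actual))],
    )
    predicted = [levels[1] if p > 0.5 else levels[0] for p in probs_pos]
    return PredictionTable(
        sample_ids=list(probs.index),
        actual_labels=list(actual),
        probabilities=probs,
        predicted_labels=predicted,
    )


class TestAuroc:
    def test_worked_example(self):
        # positives {0.9, 0.4}, negatives {0.5, 0.1}: 3 of 4 pairs correct
        value = auroc([0.9, 0.4, 0.5, 0.1], [True, True, False, False])
        assert value == pytest.approx(0.75, abs=1e-15)

    def test_all_ties_give_half(self):
        assert auroc([0.3] * 6, [True, False] * 3) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [True, True, False, False]) == 1.0

    def test_single_class_truth_is_nan(self):
        assert math.isnan(auroc([0.1, 0.9], [True, True]))

    def test_agrees_with_pairwise_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = rng.integers(4, 50)
            scores = rng.choice(np.round(rng.random(8), 2), n)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.random(30)
        labels = rng.random(30) < 0.4
        assert auroc(np.exp(3 * scores), labels) == pytest.approx(
            auroc(scores, labels), abs=1e-12
        )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores, labels = rng.random(50), rng.random(50) < 0.5
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestBrier:
    def test_perfect_and_constant(self):
        assert brier([1.0, 0.0], [True, False]) == 0.0
        assert brier([0.5] * 4, [True, False, True, False]) == pytest.approx(0.25)

    def test_worked_example(self):
        assert brier([0.8, 0.3], [True, False]) == pytest.approx(0.065)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            brier([1.2], [True])


class TestDerivedMetrics:
    def test_mcc_worked_example(self):
        values = derived_metrics(ConfusionCounts(tp=2, fp=1, tn=3, fn=1))
        assert values["mcc"] == pytest.approx(5 / 12)

    def test_f1_worked_example(self):
        values = derived_metrics(ConfusionCounts(tp=2, fp=1, tn=0, fn=1))
        assert values["f1"] == pytest.approx(2 / 3)

    def test_symmetric_counts_mcc_zero(self):
        assert derived_metrics(ConfusionCounts(1, 1, 1, 1))["mcc"] == 0.0

    def test_zero_over_zero_yields_zero(self):
        values = derived_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert values["ppv"] == 0.0 and values["f1"] == 0.0

    def test_algebraic_identities_on_random_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            tp, fp, tn, fn = rng.integers(0, 40, 4)
            if tp + fp + tn + fn == 0:
                continue
            v = derived_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert v["accuracy"] + v["mmce"] == pytest.approx(1.0)
            assert v["fdr"] == pytest.approx(1.0 - v["ppv"])
            assert v["fpr"] == pytest.approx(1.0 - v["tnr"])
            assert v["fnr"] == pytest.approx(1.0 - v["tpr"])
            assert v["balanced_accuracy"] == pytest.approx((v["tpr"] + v["tnr"]) / 2)
            assert v["recall"] == v["tpr"]
            assert -1.0 <= v["mcc"] <= 1.0

    def test_agrees_with_sklearn_mcc(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(12)
        actual = rng.integers(0, 2, 40)
        predicted = rng.integers(0, 2, 40)
        counts = ConfusionCounts(
            tp=int(((actual == 1) & (predicted == 1)).sum()),
            fp=int(((actual == 0) & (predicted == 1)).sum()),
            tn=int(((actual == 0) & (predicted == 0)).sum()),
            fn=int(((actual == 1) & (predicted == 0)).sum()),
        )
        assert derived_metrics(counts)["mcc"] == pytest.approx(
            matthews_corrcoef(actual, predicted), abs=1e-12
        )


class TestConfusion:
    def test_direct_counting(self):
        table = table_from(["pos", "pos", "neg", "neg"], [0.9, 0.1, 0.9, 0.1])
        counts = confusion(table, "pos")
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (1, 1, 1, 1)
        assert counts.n == 4

    def test_unknown_class_errors(self):
        table = table_from(["pos", "neg"], [0.9, 0.1])
        with pytest.raises(ValueError):
            confusion(table, "maybe")


class TestScorePredictions:
    def test_emits_all_fifteen_metrics(self):
        records = score_predictions(table_from(["pos", "neg"], [0.9, 0.1]))
        assert sorted(r.metric for r in records) == sorted(METRIC_IDS)
        assert len(records) == 15

    def test_binary_perfect_prediction(self):
        records = score_predictions(
            table_from(["pos", "pos", "neg", "neg"], [0.9, 0.8, 0.2, 0.1])
        )
        values = {r.metric: r.value for r in records}
        assert values["accuracy"] == 1.0
        assert values["mmce"] == 0.0
        assert values["auroc"] == 1.0
        assert values["mcc"] == 1.0

    def test_binary_positive_class_is_lexicographically_second(self):
        # "pos" > "neg", so tpr must be the recall of "pos"
        table = table_from(["pos", "pos", "neg"], [0.9, 0.1, 0.2])
        values = {r.metric: r.value for r in score_predictions(table)}
        assert values["tpr"] == pytest.approx(0.5)

    def test_multiclass_macro_average(self):
        levels = ["a", "b", "c"]
        probs = pd.DataFrame(
            [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6], [0.5, 0.3, 0.2]],
            columns=levels,
            index=["s0", "s1", "s2", "s3"],
        )
        table = PredictionTable(
            sample_ids=list(probs.index),
            actual_labels=["a", "b", "c", "b"],
            probabilities=probs,
            predicted_labels=[levels[i] for i in probs.to_numpy().argmax(axis=1)],
        )
        records = {r.metric: r.value for r in score_predictions(table)}
        per_class = []
        for level in levels:
            counts = confusion(table, level)
            per_class.append(derived_metrics(counts)["accuracy"])
        assert records["accuracy"] == pytest.approx(np.mean(per_class))

    def test_sample_order_invariance(self):
        table = table_from(["pos", "neg", "pos", "neg"], [0.7, 0.4, 0.6, 0.2])
        shuffled = table_from(["neg", "pos", "neg", "pos"], [0.2, 0.7, 0.4, 0.6])
        a = {r.metric: r.value for r in score_predictions(table)}
        b = {r.metric: r.value for r in score_predictions(shuffled)}
        for metric in METRIC_IDS:
            assert a[metric] == pytest.approx(b[metric], nan_ok=True)
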