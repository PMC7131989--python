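import numpy as np
import pandas as pd
import pytest

from cvbench.algorithms import ClassifierSpec, RankerSpec, default_spec
from cvbench.crossval import (
    BenchmarkPlan,
    StratificationError,
    effective_feature_grid,
    kfold_splits,
    monte_carlo_splits,
    run_basic,
    run_nested,
    select_best_combo,
    select_best_feature_count,
    _nested_splits,
)
from cvbench.reporting import write_all
from cvbench.synthetic import NullSpec, SignalSpec, generate_null, generate_signal

from conftest import separable_dataset


def labels(n, n_classes=2, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.choice([f"c{k}" for k in range(n_classes)], n)
    values[:n_classes] = [f"c{k}" for k in range(n_classes)]
    return pd.Series(values, index=[f"s{i}" for i in range(n)])


class TestMonteCarloSplits:
    def test_train_size_rounding(self):
        y = pd.Series(["a"] * 6 + ["b"] * 3, index=[f"s{i}" for i in range(9)])
        for split in monte_carlo_splits(y, iterations=3, train_fraction=2 / 3, seed=1):
            assert len(split.train_ids) == 6
            assert len(split.validation_ids) == 3

    def test_partition_property(self):
        y = labels(31, n_classes=3, seed=2)
        for split in monte_carlo_splits(y, 5, 0.7, seed=3):
            train, val = set(split.train_ids), set(split.validation_ids)
            assert train.isdisjoint(val)
            assert train | val == set(y.index)
            assert train and val

    def test_stratification_preserves_proportions(self):
        y = pd.Series(["a"] * 40 + ["b"] * 20, index=[f"s{i}" for i in range(60)])
        for split in monte_carlo_splits(y, 3, 0.5, seed=4):
            train_labels = y.loc[list(split.train_ids)]
            assert (train_labels == "a").sum() == 20
            assert (train_labels == "b").sum() == 10

    def test_both_sides_see_every_class(self):
        y = pd.Series(["a"] * 18 + ["b"] * 2, index=[f"s{i}" for i in range(20)])
        for split in monte_carlo_splits(y, 10, 0.9, seed=5):
            assert set(y.loc[list(split.train_ids)]) == {"a", "b"}
            assert set(y.loc[list(split.validation_ids)]) == {"a", "b"}

    def test_seed_determinism(self):
        y = labels(25, seed=6)
        assert monte_carlo_splits(y, 4, 2 / 3, seed=7) == monte_carlo_splits(
            y, 4, 2 / 3, seed=7
        )
        assert monte_carlo_splits(y, 4, 2 / 3, seed=7) != monte_carlo_splits(
            y, 4, 2 / 3, seed=8
        )

    def test_tiny_class_errors(self):
        y = pd.Series(["a", "a", "a", "b"], index=list("wxyz"))
        with pytest.raises(StratificationError):
            monte_carlo_splits(y, 2, 0.5, seed=0)


class TestKfoldSplits:
    def test_even_partition(self):
        y = labels(10, seed=1)
        splits = kfold_splits(y, k=5, seed=1)
        sizes = [len(s.validation_ids) for s in splits]
        assert sizes == [2] * 5

    def test_near_even_partition(self):
        y = pd.Series(["a"] * 6 + ["b"] * 5, index=[f"s{i}" for i in range(11)])
        sizes = sorted(len(s.validation_ids) for s in kfold_splits(y, 5, seed=2))
        assert sizes == [2, 2, 2, 2, 3]

    def test_validation_sets_partition_samples(self):
        y = labels(23, n_classes=2, seed=3)
        splits = kfold_splits(y, 4, seed=3)
        seen = [sid for s in splits for sid in s.validation_ids]
        assert sorted(seen) == sorted(y.index)

    def test_k_larger_than_n_errors(self):
        with pytest.raises(ValueError):
            kfold_splits(labels(4), k=9, seed=0)

    def test_class_smaller_than_k_errors(self):
        y = pd.Series(["a"] * 8 + ["b"] * 2, index=[f"s{i}" for i in range(10)])
        with pytest.raises(StratificationError):
            kfold_splits(y, k=3, seed=0)


class TestRandomPlanPartitions:
    def test_partitions_hold_over_random_plans(self):
        """Disjointness and coverage for many randomly drawn plans."""
        rng = np.random.default_rng(99)
        for trial in range(60):
            n = int(rng.integers(12, 60))
            n_classes = int(rng.integers(2, 4))
            y = labels(n, n_classes=n_classes, seed=trial)
            if min((y == c).sum() for c in y.unique()) < 4:
                continue
            if rng.random() < 0.5:
                splits = monte_carlo_splits(
                    y, int(rng.integers(1, 5)), float(rng.uniform(0.4, 0.8)), seed=trial
                )
            else:
                k = int(rng.integers(2, min(4, min((y == c).sum() for c in y.unique())) + 1))
                splits = kfold_splits(y, k, seed=trial)
            for split in splits:
                train, val = set(split.train_ids), set(split.validation_ids)
                assert train.isdisjoint(val)
                assert train | val == set(y.index)


class TestPlanValidation:
    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            BenchmarkPlan(train_fraction=1.2)

    def test_rejects_non_increasing_grid(self):
        with pytest.raises(ValueError):
            BenchmarkPlan(feature_count_grid=(5, 3))

    def test_rejects_unknown_metric(self):
        with pytest.raises(ValueError):
            BenchmarkPlan(selection_metric="aurocc")


def test_effective_grid_clipping():
    assert effective_feature_grid((1, 3, 5, 10, 15, 20, 50, 200), 14) == [1, 3, 5, 10]
    assert effective_feature_grid((5,), 20) == [5]
    assert effective_feature_grid((50, 200), 7) == [7]  # all too large -> use F


class TestRunBasic:
    def test_bookkeeping_one_cell(self, separable):
        plan = BenchmarkPlan(outer_count=1, seed=2)
        result = run_basic(separable, [default_spec("sklearn/gaussian_nb")], plan)
        assert len(result.cells) == 1
        cell = result.cells[0]
        expected_val = set(separable.sample_ids) - set(
            monte_carlo_splits(separable.y, 1, 2 / 3, 2)[0].train_ids
        )
        assert set(cell.predictions.sample_ids) == expected_val
        assert cell.elapsed_seconds > 0

    def test_perfect_learner_on_separable_data(self, separable):
        plan = BenchmarkPlan(outer_count=2, seed=3)
        result = run_basic(separable, [default_spec("sklearn/logistic_regression")], plan)
        for cell in result.cells:
            values = {m.metric: m.value for m in cell.metrics}
            assert values["auroc"] == 1.0
            assert values["mmce"] == 0.0

    def test_cell_failure_is_recorded_not_fatal(self, separable):
        bad = ClassifierSpec("sklearn/svm", "broken", {"C": -1.0})
        good = default_spec("sklearn/gaussian_nb")
        plan = BenchmarkPlan(outer_count=2, seed=4)
        result = run_basic(separable, [bad, good], plan)
        failed = [c for c in result.cells if c.error]
        ok = [c for c in result.cells if not c.error]
        assert len(failed) == 2 and len(ok) == 2


class TestNestedSelection:
    def test_single_combo_chosen_with_records(self, separable):
        plan = BenchmarkPlan(outer_count=1, nested_count=2, seed=5)
        combo = default_spec("sklearn/gaussian_nb")
        chosen, records = select_best_combo(
            separable, "sklearn/gaussian_nb", [combo], plan
        )
        assert chosen == combo
        assert len(records) == 2  # one per inner iteration
        assert all(r.chosen for r in records)

    def test_real_learner_beats_near_constant_dummy(self, separable):
        # C=1e-10 regularizes logistic regression into a near-constant
        # predictor; on separable data the default combo must dominate it
        plan = BenchmarkPlan(outer_count=1, nested_count=3, seed=6)
        combos = [
            ClassifierSpec("sklearn/logistic_regression", "dummy-like", {"C": 1e-10}),
            default_spec("sklearn/logistic_regression"),
        ]
        chosen, records = select_best_combo(
            separable, "sklearn/logistic_regression", combos, plan
        )
        assert chosen.combo_id == "default"
        chosen_ids = {r.combo_id for r in records if r.chosen}
        assert chosen_ids == {"default"}

    def test_nested_ids_stay_inside_outer_train(self):
        d = generate_null(NullSpec(n_samples=60, seed=7))
        plan = BenchmarkPlan(outer_count=3, nested_count=3, seed=7)
        for outer in monte_carlo_splits(d.y, 3, plan.train_fraction, plan.seed):
            train = d.subset(outer.train_ids)
            for inner in _nested_splits(train, plan, outer.iteration):
                inner_ids = set(inner.train_ids) | set(inner.validation_ids)
                assert inner_ids <= set(outer.train_ids)
                assert inner_ids.isdisjoint(outer.validation_ids)

    def test_feature_count_single_option(self, separable):
        plan = BenchmarkPlan(
            outer_count=1, nested_count=2, feature_count_grid=(2,), seed=8
        )
        count, rankings, records = select_best_feature_count(
            separable, RankerSpec("sklearn/anova"),
            default_spec("sklearn/gaussian_nb"), plan,
        )
        assert count == 2
        assert len(rankings) == 2
        assert {r.feature_count for r in records} == {"2"}

    def test_planted_signal_chooses_small_count(self):
        d, _ = generate_signal(
            SignalSpec(n_samples=150, n_categorical=0, informative_features=3,
                       effect_size=2.0, seed=9)
        )
        plan = BenchmarkPlan(outer_count=1, nested_count=3,
                             feature_count_grid=(1, 3, 5, 10, 15, 20), seed=9)
        count, _, _ = select_best_feature_count(
            d, RankerSpec("sklearn/anova"), default_spec("sklearn/logistic_regression"),
            plan,
        )
        assert count <= 5


class TestDegenerateNestingEquivalence:
    def test_single_option_nested_reproduces_basic_byte_for_byte(self, tmp_path):
        d = generate_null(NullSpec(n_samples=60, seed=10))
        algorithm = "sklearn/gaussian_nb"
        basic = run_basic(
            d, [default_spec(algorithm)], BenchmarkPlan(outer_count=3, seed=11)
        )
        nested = run_nested(
            d, [algorithm], BenchmarkPlan(outer_count=3, nested_count=2, seed=11),
            combos_by_algorithm={algorithm: [default_spec(algorithm)]},
        )
        basic_paths = write_all(basic, tmp_path / "basic")
        nested_paths = write_all(nested, tmp_path / "nested")
        for name in ("predictions", "metrics"):
            assert basic_paths[name].read_bytes() == nested_paths[name].read_bytes()

    def test_rerun_is_byte_identical(self, tmp_path):
        d = generate_null(NullSpec(n_samples=50, seed=12))
        plan = BenchmarkPlan(outer_count=2, seed=13)
        specs = [default_spec("sklearn/gaussian_nb")]
        first = write_all(run_basic(d, specs, plan), tmp_path / "a")
        second = write_all(run_basic(d, specs, plan), tmp_path / "b")
        for name in ("predictions", "metrics", "nested", "feature_ranks"):
            assert first[name].read_bytes() == second[name].read_bytes()


class TestRunNested:
    def test_leakage_freedom_outer_validation_never_in_nested(self):
        d = generate_null(NullSpec(n_samples=60, seed=14))
        plan = BenchmarkPlan(outer_count=2, nested_count=2, seed=14)
        result = run_nested(
            d, ["sklearn/gaussian_nb"], plan,
            rankers=[RankerSpec("sklearn/anova")],
        )
        outer = {
            s.iteration: set(s.validation_ids)
            for s in monte_carlo_splits(d.y, 2, plan.train_fraction, plan.seed)
        }
        for cell in result.cells:
            assert cell.error is None
            assert set(cell.predictions.sample_ids) == outer[cell.iteration]

    def test_chosen_flag_unique_per_cell(self):
        d = generate_null(NullSpec(n_samples=60, seed=15))
        plan = BenchmarkPlan(outer_count=2, nested_count=2, seed=15)
        result = run_nested(d, ["sklearn/gaussian_nb"], plan)
        frame = pd.DataFrame(
            [
                {
                    "outer": r.outer_iteration,
                    "combo": r.combo_id,
                    "chosen": r.chosen,
                }
                for r in result.nested_records
            ]
        )
        for outer, group in frame.groupby("outer"):
            assert group[group.chosen].combo.nunique() == 1
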