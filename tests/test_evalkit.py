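import numpy as np
import pandas as pd
import pytest

from pleurakit import (CapabilityError, ConfusionCounts, EnhanceConfig,
                       ParameterError, PhantomConfig, PipelineConfig,
                       SplitSpec, TrainConfig, classification_metrics,
                       column_mean_percent, confusion_matrix, generate_samples,
                       input_mode_grid, kfold_cross_validate,
                       metrics_from_labels, run_comparison, stratified_split,
                       train_classifier)
from pleurakit.tinycnn import make_backbone
from oracles import metrics_by_hand

SMALL = PhantomConfig(image_size=(128, 128))


@pytest.fixture(scope="module")
def small_cohort():
    return generate_samples(8, SMALL, seed=21, fill_range=(0.4, 0.7))


class TestConfusionMatrix:
    def test_perfect_prediction(self):
        cm = confusion_matrix(["+", "+", "-", "-"], ["+", "+", "-", "-"], "+")
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 0, 0, 2)

    def test_all_positive_predictions(self):
        cm = confusion_matrix(["+", "+"], ["+", "-"], "+")
        assert (cm.tp, cm.fp) == (1, 1)

    def test_matches_pairwise_tally(self, rng):
        pred = rng.choice(["a", "b"], size=50)
        true = rng.choice(["a", "b"], size=50)
        cm = confusion_matrix(pred, true, "a")
        tp = sum(p == "a" and t == "a" for p, t in zip(pred, true))
        fp = sum(p == "a" and t == "b" for p, t in zip(pred, true))
        fn = sum(p == "b" and t == "a" for p, t in zip(pred, true))
        tn = sum(p == "b" and t == "b" for p, t in zip(pred, true))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (tp, fp, fn, tn)

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            confusion_matrix(["a"], ["a", "b"], "a")
        with pytest.raises(ParameterError):
            confusion_matrix(["a", "b", "c"], ["a", "b", "c"], "a")


class TestClassificationMetrics:
    def test_hand_worked_example(self):
        m = classification_metrics(ConfusionCounts(3, 1, 2, 4),
                                   "per_positive_class")
        assert np.isclose(m.accuracy, 0.7)
        assert np.isclose(m.precision, 0.75)
        assert np.isclose(m.recall, 0.6)
        assert np.isclose(m.f1, 2 / 3)

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(5, 0, 0, 5), "macro")
        assert m.accuracy == m.precision == m.recall == m.f1 == 1.0

    def test_random_counts_match_hand_arithmetic(self, rng):
        for _ in range(1000):
            tp, fp, fn, tn = rng.integers(0, 40, size=4)
            if tp + fp + fn + tn == 0:
                continue
            m = classification_metrics(ConfusionCounts(tp, fp, fn, tn),
                                       "per_positive_class")
            acc, prec, rec, f1 = metrics_by_hand(tp, fp, fn, tn)
            assert np.allclose([m.accuracy, m.precision, m.recall, m.f1],
                               [acc, prec, rec, f1])

    def test_macro_recall_equals_accuracy_when_balanced(self, rng):
        """On balanced truth labels, macro recall reduces to accuracy —
        the reason accuracy and recall rows coincide in balanced tables."""
        for _ in range(200):
            n = int(rng.integers(2, 40))
            truth = ["pos"] * n + ["neg"] * n
            pred = list(rng.choice(["pos", "neg"], size=2 * n))
            m = metrics_from_labels(pred, truth, "macro")
            assert np.isclose(m.recall, m.accuracy)

    def test_zero_denominator_reports_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            m = classification_metrics(ConfusionCounts(0, 0, 5, 5),
                                       "per_positive_class")
        assert m.precision == 0.0 and m.f1 == 0.0


class TestColumnMean:
    def test_half_up_decimal_rounding(self):
        # float arithmetic would give 81.244999... -> 81.24; the printed
        # convention averages the decimals exactly and rounds half up
        assert column_mean_percent([79.87, 82.62]) == 81.25
        assert column_mean_percent([66.30, 73.37]) == 69.84
        assert column_mean_percent([61.99, 71.34]) == 66.67


class TestStratifiedSplit:
    def test_clinical_scale_arithmetic(self):
        manifest = [("x", "normal")] * 461 + [("y", "effusion")] * 461
        train, val = stratified_split(manifest, SplitSpec(0.8, seed=0))
        assert len(train) == 738 and len(val) == 184
        for part, size in ((train, 369), (val, 92)):
            labels = [lab for _, lab in part]
            assert labels.count("normal") == size and labels.count("effusion") == size

    def test_exact_division(self):
        manifest = [("a", 0)] * 10 + [("b", 1)] * 10
        train, val = stratified_split(manifest, SplitSpec(0.8, seed=1))
        assert len(train) == 16 and len(val) == 4

    def test_partition_property(self):
        manifest = [(i, i % 2) for i in range(37)]
        train, val = stratified_split(manifest, SplitSpec(0.7, seed=3))
        ids = sorted(i for i, _ in train) + sorted(i for i, _ in val)
        assert sorted(ids) == list(range(37))
        assert not (set(i for i, _ in train) & set(i for i, _ in val))

    def test_seed_reproducible(self):
        manifest = [(i, "ab"[i % 2]) for i in range(20)]
        assert stratified_split(manifest, SplitSpec(seed=5)) == \
            stratified_split(manifest, SplitSpec(seed=5))

    def test_dataframe_input(self):
        df = pd.DataFrame({"filename": [f"f{i}" for i in range(10)],
                           "label": ["a", "b"] * 5})
        train, val = stratified_split(df, SplitSpec(0.8, seed=0))
        assert len(train) == 8 and len(val) == 2

    def test_tiny_class_rejected(self):
        with pytest.raises(ParameterError):
            stratified_split([("a", 0), ("b", 1), ("c", 1)], SplitSpec())


class TestCrossValidation:
    def test_fold_count_and_mean_bounds(self, small_cohort):
        report = kfold_cross_validate(small_cohort, k=4, seed=0)
        assert report.k == 4
        accs = [m.accuracy for m in report.folds]
        assert min(accs) <= report.mean["accuracy"] <= max(accs)

    def test_deterministic_given_seed(self, small_cohort):
        a = kfold_cross_validate(small_cohort, k=4, seed=3)
        b = kfold_cross_validate(small_cohort, k=4, seed=3)
        assert a == b

    def test_easy_phantoms_are_learnable(self, small_cohort):
        report = kfold_cross_validate(small_cohort, k=4, seed=0)
        assert report.mean["accuracy"] >= 0.85

    def test_insufficient_samples_rejected(self, small_cohort):
        four_per_class = small_cohort[:4] + small_cohort[-4:]
        with pytest.raises(ParameterError):
            kfold_cross_validate(four_per_class, k=5)


class TestTrainClassifier:
    def test_fit_to_train_sanity(self, small_cohort):
        model = train_classifier(small_cohort, seed=0)
        pred = model.predict(small_cohort)
        truth = [s.label for s in small_cohort]
        acc = np.mean([p == t for p, t in zip(pred, truth)])
        assert acc >= 0.9

    def test_deterministic_predictions(self, small_cohort):
        m1 = train_classifier(small_cohort, seed=1)
        m2 = train_classifier(small_cohort, seed=1)
        assert m1.predict(small_cohort) == m2.predict(small_cohort)

    def test_unavailable_backbone_lists_installed(self):
        with pytest.raises(CapabilityError, match="tinycnn"):
            make_backbone("efficientnet_b0")
        with pytest.raises(ParameterError):
            make_backbone("resnet50")

    def test_empty_training_set_rejected(self):
        with pytest.raises(ParameterError):
            train_classifier([])


class TestRunComparison:
    def test_single_cell_equals_kfold(self, small_cohort):
        cfg = PipelineConfig()
        table = run_comparison(small_cohort, {"only": cfg}, k=4, seed=0)
        report = kfold_cross_validate(small_cohort, 4, cfg, seed=0)
        assert np.isclose(table.loc["accuracy", "only"],
                          round(100 * report.mean["accuracy"], 2))

    def test_average_lungs_column_is_column_mean(self, small_cohort):
        table = run_comparison(small_cohort, input_mode_grid(), k=4, seed=0)
        for metric in table.index:
            expected = column_mean_percent([table.loc[metric, "left_lung"],
                                            table.loc[metric, "right_lung"]])
            assert table.loc[metric, "average_lungs"] == expected

    def test_deterministic(self, small_cohort):
        grid = {"a": PipelineConfig(),
                "b": PipelineConfig(enhance=EnhanceConfig("none", "none"))}
        t1 = run_comparison(small_cohort, grid, k=4, seed=2)
        t2 = run_comparison(small_cohort, grid, k=4, seed=2)
        assert t1.equals(t2)

    def test_empty_grid_rejected(self, small_cohort):
        with pytest.raises(ParameterError):
            run_comparison(small_cohort, {}, k=2)
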