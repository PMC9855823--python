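"""Cross-validation protocol, metric formulas and the experiment driver."""

import dataclasses

import numpy as np
import pytest
from sklearn.metrics import precision_score, recall_score, roc_auc_score

from stressrp.evaluation import (
    ConfusionCounts,
    EvalReport,
    ExperimentConfig,
    GridSearchSpace,
    classification_metrics,
    confusion_counts,
    grid_search,
    loro_split,
    roc_auc,
    run_experiment,
)
from stressrp.models import TrainConfig
from stressrp.synthetic import SimParams, simulate_cohort


class TestLoroSplit:
    def test_nine_recordings_nine_folds_train_size_eight(self):
        ids = [f"rec{i:02d}" for i in range(1, 10)]
        folds = loro_split(ids)
        assert len(folds) == 9
        assert all(len(train) == 8 for train, _ in folds)

    def test_two_recordings_boundary(self):
        assert len(loro_split(["a", "b"])) == 2

    def test_partition_property(self):
        ids = ["r3", "r1", "r2", "r5", "r4"]
        folds = loro_split(ids)
        test_ids = [test for _, test in folds]
        assert sorted(test_ids) == sorted(ids)
        assert len(set(test_ids)) == len(ids)
        for train, test in folds:
            assert test not in train
            assert sorted(train + [test]) == sorted(ids)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            loro_split(["a", "a", "b"])

    def test_single_recording_rejected(self):
        with pytest.raises(ValueError):
            loro_split(["only"])


class TestConfusionCounts:
    def test_perfect_predictions(self):
        y = ["stressed"] * 10 + ["relaxed"] * 10
        c = confusion_counts(y, y)
        assert (c.xp, c.xn, c.yp, c.yn) == (10, 10, 0, 0)

    def test_all_predicted_stressed(self):
        y = ["stressed"] * 10 + ["relaxed"] * 10
        c = confusion_counts(y, ["stressed"] * 20)
        assert (c.xp, c.xn, c.yp, c.yn) == (10, 0, 10, 0)

    def test_matches_brute_force_tally(self, rng):
        classes = np.array(["relaxed", "stressed"])
        y_true = list(classes[rng.integers(0, 2, 50)])
        y_pred = list(classes[rng.integers(0, 2, 50)])
        c = confusion_counts(y_true, y_pred)
        xp = sum(t == "stressed" and p == "stressed"
                 for t, p in zip(y_true, y_pred))
        xn = sum(t == "relaxed" and p == "relaxed"
                 for t, p in zip(y_true, y_pred))
        yp = sum(t == "relaxed" and p == "stressed"
                 for t, p in zip(y_true, y_pred))
        yn = sum(t == "stressed" and p == "relaxed"
                 for t, p in zip(y_true, y_pred))
        assert (c.xp, c.xn, c.yp, c.yn) == (xp, xn, yp, yn)
        assert c.total == 50

    def test_length_mismatch_and_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(["stressed"], [])
        with pytest.raises(ValueError):
            confusion_counts(["stressed"], ["calm"])


class TestMetrics:
    def test_direct_substitution(self):
        m = classification_metrics(ConfusionCounts(xp=50, xn=30, yp=10,
                                                   yn=10))
        assert m.accuracy == pytest.approx(80.0)
        assert m.precision == pytest.approx(100 * 50 / 60)
        assert m.recall == pytest.approx(100 * 50 / 60)
        assert m.f1 == pytest.approx(100 * 50 / 60)

    def test_f1_equals_precision_when_equal_to_recall(self):
        m = classification_metrics(ConfusionCounts(xp=30, xn=50, yp=10,
                                                   yn=10))
        assert m.precision == m.recall
        assert m.f1 == pytest.approx(m.precision)

    def test_matches_sklearn_on_random_counts(self, rng):
        for _ in range(20):
            y_true = rng.integers(0, 2, 60)
            y_pred = rng.integers(0, 2, 60)
            labels = np.array(["relaxed", "stressed"])
            c = confusion_counts(labels[y_true], labels[y_pred])
            m = classification_metrics(c)
            assert m.precision == pytest.approx(
                100 * precision_score(y_true, y_pred, zero_division=0))
            assert m.recall == pytest.approx(
                100 * recall_score(y_true, y_pred, zero_division=0))
            assert m.accuracy == pytest.approx(
                100 * np.mean(y_true == y_pred))

    def test_zero_denominators_define_zero(self):
        m = classification_metrics(ConfusionCounts(xp=0, xn=5, yp=0, yn=0))
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = ["relaxed", "relaxed", "stressed", "stressed"]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0

    def test_all_equal_scores_give_half(self):
        labels = ["relaxed", "stressed"] * 5
        assert roc_auc([0.5] * 10, labels) == 0.5

    def test_pair_counting_example(self):
        labels = ["relaxed", "relaxed", "stressed", "stressed"]
        assert roc_auc([0.1, 0.4, 0.35, 0.8], labels) == pytest.approx(0.75)

    def test_matches_sklearn_and_monotone_invariance(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            s = rng.random(40)
            labels = list(np.array(["relaxed", "stressed"])[y])
            auc = roc_auc(s, labels)
            assert auc == pytest.approx(roc_auc_score(y, s))
            assert roc_auc(np.exp(5 * s), labels) == pytest.approx(auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], ["stressed", "stressed"])


class TestGridSearch:
    def test_singleton_space_returned_without_search(self):
        space = GridSearchSpace(learning_rates=(0.001,), batch_sizes=(4,),
                                epochs=(15,))

        def exploding_protocol(dataset, config):
            raise AssertionError("protocol must not be called")

        config = grid_search(space, dataset=[1], protocol=exploding_protocol)
        assert (config.learning_rate, config.batch_size,
                config.epochs) == (0.001, 4, 15)

    def test_higher_validation_accuracy_wins(self):
        space = GridSearchSpace(learning_rates=(0.001, 0.01),
                                batch_sizes=(4,), epochs=(5,))

        def rigged(dataset, config):
            return 0.9 if config.learning_rate == 0.01 else 0.6

        assert grid_search(space, [1], rigged).learning_rate == 0.01

    def test_tie_breaks_lexicographically(self):
        space = GridSearchSpace(learning_rates=(0.01, 0.001),
                                batch_sizes=(4, 2), epochs=(5,))
        config = grid_search(space, [1], lambda d, c: 0.5)
        assert (config.learning_rate, config.batch_size) == (0.001, 2)

    def test_chosen_operating_point_inside_default_space(self):
        space = GridSearchSpace()
        assert 0.001 in space.learning_rates
        assert 4 in space.batch_sizes
        assert 15 in space.epochs

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            grid_search(GridSearchSpace(), [], lambda d, c: 0.5)


def _fast_config(**kwargs):
    defaults = dict(
        n_recordings=3,
        sim_params=SimParams(recording_duration=240.0),
        window_length_s=30.0,
        model_tags=("logistic-regression",),
        seed=3,
    )
    defaults.update(kwargs)
    return ExperimentConfig(**defaults)


class TestRunExperiment:
    def test_report_schema_and_fold_count(self):
        report = run_experiment(_fast_config())
        res = report.results["logistic-regression"]
        assert len(res["folds"]) == 3
        assert res["pooled"]["n_test"] == sum(
            row["n_test"] for row in res["folds"])
        csv_text = report.to_csv()
        assert csv_text.splitlines()[0] == EvalReport.CSV_HEADER
        assert len(csv_text.splitlines()) == 1 + 4  # 3 folds + pooled

    def test_test_folds_never_resampled(self):
        """Balancing shrinks training splits only; every test window of a
        fold is evaluated exactly once."""
        config = _fast_config(balancing="undersample")
        cohort = simulate_cohort(config.n_recordings, config.sim_params,
                                 seed=99)
        from stressrp.preprocess import segment_windows
        raw_counts = {rec.recording_id: len(segment_windows(rec, 30.0))
                      for rec in cohort.recordings}
        report = run_experiment(config, cohort)
        for row in report.results["logistic-regression"]["folds"]:
            assert row["n_test"] == raw_counts[row["test_recording"]]

    def test_classifies_separable_cohort_well(self):
        report = run_experiment(_fast_config(model_tags=("xgboost",)))
        assert report.pooled_accuracy("xgboost") > 85.0

    def test_oversampling_balances_training_split(self):
        report = run_experiment(_fast_config(balancing="oversample"))
        for row in report.results["logistic-regression"]["folds"]:
            assert row["n_train"] % 2 == 0

    def test_deterministic_given_master_seed(self):
        a = run_experiment(_fast_config()).to_json()
        b = run_experiment(_fast_config()).to_json()
        assert a == b

    def test_unknown_model_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown model tags"):
            _fast_config(model_tags=("perceptron",))

    def test_unknown_balancing_rejected(self):
        with pytest.raises(ValueError, match="balancing"):
            _fast_config(balancing="smote")


class TestRepeatExperiment:
    def test_mean_and_sd_over_seeds(self):
        from stressrp.evaluation import repeat_experiment

        summary = repeat_experiment(_fast_config(), seeds=[1, 2])
        entry = summary["logistic-regression"]
        assert entry["n_runs"] == 2
        assert 0.0 <= entry["accuracy_mean"] <= 100.0
        assert entry["accuracy_sd"] >= 0.0
        assert entry["auc_mean"] is not None

    def test_empty_seed_list_rejected(self):
        from stressrp.evaluation import repeat_experiment

        with pytest.raises(ValueError):
            repeat_experiment(_fast_config(), seeds=[])
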