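import warnings

import numpy as np
import pandas as pd
import pytest

from pivotshift.classify import (
    UNCLASSIFIABLE,
    SplitSpec,
    TwoStageClassifier,
    evaluate,
    make_model,
    recording_dataset,
    split_train_test,
    train_baseline_raw,
)
from pivotshift.features import extract_feature_table
from pivotshift.model import FEATURE_COLUMNS
from pivotshift.simulate import simulate_cohort


def _labelled(counts):
    rows = []
    i = 0
    for g, c in counts.items():
        for _ in range(c):
            rows.append({"case": f"C{i}", "grade": g})
            i += 1
    return pd.DataFrame(rows)


class TestSplit:
    def test_study_counts_give_nine_test_cases(self):
        train, test = split_train_test(_labelled({0: 10, 1: 9, 2: 9, 3: 2}))
        assert len(test) == 9
        assert len(train) == 21
        assert sorted(test["grade"].value_counts().to_dict().items()) == [
            (0, 3), (1, 3), (2, 3)
        ]

    def test_all_grades_eligible_give_twelve(self):
        train, test = split_train_test(_labelled({0: 3, 1: 3, 2: 3, 3: 3}))
        assert len(test) == 12
        assert len(train) == 0

    def test_deterministic(self):
        df = _labelled({0: 10, 1: 9, 2: 9, 3: 2})
        _, a = split_train_test(df, SplitSpec(seed=5))
        _, b = split_train_test(df, SplitSpec(seed=5))
        assert list(a.index) == list(b.index)

    def test_disjoint_and_exhaustive(self):
        df = _labelled({0: 10, 1: 9, 2: 9, 3: 2})
        train, test = split_train_test(df, SplitSpec(seed=1))
        assert set(train.index) | set(test.index) == set(df.index)
        assert set(train.index) & set(test.index) == set()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_train_test(pd.DataFrame(columns=["grade"]))


class TestEvaluate:
    def test_all_correct(self):
        rep = evaluate([0, 1, 2, 3], [0, 1, 2, 3])
        assert rep.accuracy == 100.0
        assert rep.f1 == 1.0
        assert rep.classifiability_ratio == 1.0

    def test_confusion_matrix_example(self):
        # truth/prediction pairs realizing the matrix [[2, 1], [0, 3]]
        preds = [0, 0, 1, 1, 1, 1]
        truth = [0, 0, 0, 1, 1, 1]
        rep = evaluate(preds, truth)
        assert rep.confusion_matrix.tolist() == [[2, 1], [0, 3]]
        assert rep.accuracy == pytest.approx(100 * 5 / 6)
        assert rep.recall == rep.precision == rep.accuracy
        assert rep.f1 == pytest.approx(5 / 6)

    def test_metrics_recomputable_from_matrix(self):
        rng = np.random.default_rng(0)
        preds = rng.integers(0, 4, 50)
        truth = rng.integers(0, 4, 50)
        rep = evaluate(preds, truth)
        cm = rep.confusion_matrix
        assert cm.sum() == rep.n_test == 50
        assert rep.accuracy == pytest.approx(100.0 * np.trace(cm) / cm.sum())

    def test_classifiability_ratio(self):
        preds = [0] * 27 + [UNCLASSIFIABLE] * 3
        truth = [0] * 30
        rep = evaluate(preds, truth)
        assert rep.classifiability_ratio == pytest.approx(0.9)
        assert rep.n_test == 27
        assert rep.n_total == 30

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate([0, 1], [0])


class TestBaselineRaw:
    def _signals(self, rng, n, length=500, offset=0.0):
        return [offset + rng.normal(size=length) for _ in range(n)]

    def test_perfectly_separable_two_grades(self):
        rng = np.random.default_rng(1)
        X = self._signals(rng, 10, offset=0.0) + self._signals(rng, 10, offset=30.0)
        y = [0] * 10 + [1] * 10
        model = train_baseline_raw(X, y, "svm", seed=0)
        Xte = self._signals(rng, 5, offset=0.0) + self._signals(rng, 5, offset=30.0)
        yte = [0] * 5 + [1] * 5
        assert np.mean(model.predict(np.vstack(Xte)) == yte) == 1.0

    def test_shuffled_labels_hit_chance_level(self):
        """Permuted labels leave nothing to learn: accuracy ~ 25% for 4 grades."""
        rng = np.random.default_rng(2)
        X = np.vstack(self._signals(rng, 40, length=120))
        y = np.tile([0, 1, 2, 3], 10)  # any contiguous slice stays balanced
        accs = []
        for _ in range(100):
            shuffled = rng.permutation(y)
            model = train_baseline_raw(X[:24], shuffled[:24], "lr", seed=0)
            accs.append(np.mean(model.predict(X[24:]) == y[24:]))
        assert np.mean(accs) == pytest.approx(0.25, abs=0.08)

    def test_four_grade_chance_level_is_25_percent(self):
        assert 100.0 / 4 == 25.0

    def test_mixed_lengths_rejected_without_resampling(self):
        rng = np.random.default_rng(3)
        X = [rng.normal(size=500), rng.normal(size=400)]
        with pytest.raises(ValueError, match="mixed lengths"):
            train_baseline_raw(X, [0, 1], "dt")
        model = train_baseline_raw(X, [0, 1], "dt", resample_to=500)
        assert model is not None

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            make_model("mlp")


def _dataset(seed, noise_frac=0.05):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        session, truth = simulate_cohort(
            {0: 10, 1: 9, 2: 9, 3: 2}, seed=seed, noise_frac=noise_frac
        )
        table = extract_feature_table(session)
    data = recording_dataset(table)
    data["grade"] = data["grade"].astype(int)
    return session, data


class TestTwoStage:
    def test_stage1_recovers_classes_at_low_noise(self):
        session, data = _dataset(seed=1, noise_frac=0.005)
        train, test = split_train_test(data, SplitSpec(seed=1))
        clf = TwoStageClassifier(seed=1).fit(train)
        assert np.mean(clf.predict_class(test) == test["klass"].to_numpy()) == 1.0

    def test_untrained_class_is_unclassifiable(self):
        _, data = _dataset(seed=2, noise_frac=0.005)
        train, test = split_train_test(data, SplitSpec(seed=2))
        # strip grade labels from one class: no stage-2 model can be fitted
        victim = int(test.iloc[0]["klass"])
        train = train.copy()
        train.loc[train["klass"] == victim, "grade"] = np.nan
        clf = TwoStageClassifier(seed=2).fit(train)
        preds = clf.predict(test)
        routed = clf.predict_class(test)
        assert all(
            p == UNCLASSIFIABLE for p, c in zip(preds, routed) if c == victim
        )

    def test_default_methods_are_svm_then_tree(self):
        clf = TwoStageClassifier()
        assert clf.stage1_method == "svm"
        assert clf.stage2_method == "dt"

    def test_training_is_reproducible(self):
        _, data = _dataset(seed=3)
        train, test = split_train_test(data, SplitSpec(seed=3))
        a = TwoStageClassifier(seed=3).fit(train).predict(test)
        b = TwoStageClassifier(seed=3).fit(train).predict(test)
        assert list(a) == list(b)

    def test_unfitted_predict_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            TwoStageClassifier().predict_class(np.zeros((1, 4)))


class TestEndToEndRecovery:
    def test_two_stage_beats_raw_baseline_over_seed_sweep(self):
        """Pivot-feature pipeline recovers grades; raw signals lag behind."""
        two_stage, baseline = [], []
        for seed in range(25):
            session, data = _dataset(seed=seed)
            train, test = split_train_test(data, SplitSpec(seed=seed))
            clf = TwoStageClassifier(seed=seed).fit(train)
            rep = evaluate(clf.predict(test), test["grade"].to_numpy())
            two_stage.append(rep.accuracy)

            key = ["subject_id", "evaluator_id", "repeat_index"]
            sigs = {
                (r.subject_id, r.evaluator_id, r.repeat_index): r.x
                for r in session.recordings
            }
            Xtr = [sigs[tuple(r)] for r in train[key].to_numpy()]
            Xte = [sigs[tuple(r)] for r in test[key].to_numpy()]
            model = train_baseline_raw(Xtr, train["grade"].to_numpy(), "svm", seed)
            baseline.append(
                100.0 * np.mean(model.predict(np.vstack(Xte)) == test["grade"].to_numpy())
            )
        assert min(two_stage) >= 90.0
        assert np.mean(baseline) < np.mean(two_stage)
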