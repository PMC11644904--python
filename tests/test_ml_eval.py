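"""LOSO splitting, SMOTE, tuning grids and classifier/regressor evaluation."""

import numpy as np
import pandas as pd
import pytest

from divehrv.ml_eval import (
    MODEL_GRIDS,
    SmoteConfig,
    evaluate_classifiers,
    make_loso,
    smote,
    svr_regression_eval,
    tune_first_fold,
)


def _toy_data(n_subjects=8, per_subject=10, separation=0.0, seed=0):
    """Subject-structured feature frame with optional class separation."""
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for i in range(n_subjects):
        sid = f"S{i:02d}"
        for j in range(per_subject):
            y = int(rng.uniform() < 0.35)
            x = rng.normal(0, 1, 4) + separation * y
            rows.append({"subject_id": sid, "f0": x[0], "f1": x[1], "f2": x[2], "f3": x[3]})
            labels.append(y)
    return pd.DataFrame(rows), np.array(labels)


FEATS = ["f0", "f1", "f2", "f3"]


class TestLoso:
    def test_folds_partition_subjects(self):
        data, _ = _toy_data(6)
        split = make_loso(data)
        assert len(split) == 6
        for train, test in split.folds:
            assert test not in train
            assert sorted(train + [test]) == sorted(data.subject_id.unique())
        assert sorted(t for _, t in split.folds) == sorted(data.subject_id.unique())

    def test_two_subjects_rejected(self):
        data, _ = _toy_data(2)
        with pytest.raises(ValueError):
            make_loso(data)


class TestSmote:
    def test_balances_classes_and_preserves_originals(self, rng):
        X = rng.normal(0, 1, (30, 3))
        y = np.array([0] * 24 + [1] * 6)
        Xb, yb = smote(X, y, SmoteConfig(seed=1))
        _, counts = np.unique(yb, return_counts=True)
        assert counts[0] == counts[1] == 24
        assert np.array_equal(Xb[:30], X)

    def test_synthetics_lie_on_minority_segments(self, rng):
        X = rng.normal(0, 1, (200, 2))
        y = np.array([0] * 170 + [1] * 30)
        Xb, yb = smote(X, y, SmoteConfig(seed=2))
        minority = X[y == 1]
        synth = Xb[len(X):]
        # each synthetic must lie on the segment between SOME pair of
        # minority originals: minimize the point-to-segment residual
        # over all pairs
        for s in synth:
            best = np.inf
            for i in range(len(minority)):
                for j in range(i + 1, len(minority)):
                    a, b = minority[i], minority[j]
                    seg = b - a
                    t = np.clip(np.dot(s - a, seg) / np.dot(seg, seg), 0, 1)
                    best = min(best, np.linalg.norm(a + t * seg - s))
            assert best < 1e-8

    def test_identical_minority_points_replicate(self):
        X = np.vstack([np.zeros((2, 3)) + 7.0, np.random.default_rng(0).normal(0, 1, (10, 3))])
        y = np.array([1, 1] + [0] * 10)
        Xb, yb = smote(X, y, SmoteConfig(seed=3))
        assert np.allclose(Xb[yb == 1], 7.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            smote(np.zeros((5, 2)), np.zeros(5))


class TestTuning:
    def test_grids_contain_study_operating_points(self):
        assert 3 in MODEL_GRIDS["knn"]["n_neighbors"]
        assert 1.0 in MODEL_GRIDS["kernel_svm"]["C"]
        assert 30 in MODEL_GRIDS["random_forest"]["n_estimators"]
        assert 5 in MODEL_GRIDS["random_forest"]["max_depth"]

    def test_svm_grid_spans_seven_decades(self):
        C = MODEL_GRIDS["kernel_svm"]["C"]
        assert len(C) == 7
        assert C[0] == pytest.approx(0.001) and C[-1] == pytest.approx(1000)
        assert np.allclose(np.diff(np.log10(C)), 1.0)

    def test_deterministic_given_seed(self):
        data, y = _toy_data(6, separation=2.0, seed=5)
        X = data[FEATS].to_numpy()
        a = tune_first_fold(X, y, "knn", seed=9, cv=5)
        b = tune_first_fold(X, y, "knn", seed=9, cv=5)
        assert a == b


class TestEvaluateClassifiers:
    def test_separable_classes_classified_perfectly(self):
        data, y = _toy_data(6, separation=10.0, seed=1)
        reports = evaluate_classifiers(
            data, y, FEATS, models=("knn",), seed=0, tune=False,
            params={"knn": {"n_neighbors": 3}},
        )
        assert reports[0].accuracy_mean == pytest.approx(1.0)
        assert reports[0].f1_mean == pytest.approx(1.0)

    def test_shuffled_labels_fall_to_chance(self):
        data, y = _toy_data(8, per_subject=20, separation=10.0, seed=2)
        rng = np.random.default_rng(0)
        reports = evaluate_classifiers(
            data, rng.permutation(y), FEATS, models=("knn",), seed=0, tune=False,
            params={"knn": {"n_neighbors": 3}},
        )
        assert reports[0].accuracy_mean < 0.75

    def test_report_shape_and_metric_ranges(self):
        data, y = _toy_data(6, separation=1.0, seed=3)
        reports = evaluate_classifiers(
            data, y, FEATS, seed=0, tune=False,
            params={
                "knn": {"n_neighbors": 3},
                "kernel_svm": {"C": 1.0},
                "linear_svm": {"C": 1.0},
                "random_forest": {"n_estimators": 30, "max_depth": 5},
            },
        )
        assert {r.model for r in reports} == {
            "random_forest", "kernel_svm", "linear_svm", "knn",
        }
        for r in reports:
            assert all(0 <= a <= 1 for a in r.fold_accuracy)
            assert min(r.fold_accuracy) <= r.accuracy_mean <= max(r.fold_accuracy)

    def test_no_test_fold_leakage(self):
        # poisoning the held-out subject's rows must not change what the
        # model learned from the training subjects
        data, y = _toy_data(5, separation=3.0, seed=4)
        test_subj = sorted(data.subject_id.unique())[0]
        poisoned = data.copy()
        poisoned.loc[poisoned.subject_id == test_subj, FEATS] = 1e9

        from divehrv.ml_eval import _fold_arrays
        from sklearn.preprocessing import StandardScaler

        train = [s for s in sorted(data.subject_id.unique()) if s != test_subj]
        Xtr_a, ytr_a, _, _ = _fold_arrays(data, y, FEATS, train, test_subj)
        Xtr_b, ytr_b, _, _ = _fold_arrays(poisoned, y, FEATS, train, test_subj)
        assert np.array_equal(Xtr_a, Xtr_b) and np.array_equal(ytr_a, ytr_b)
        sa = StandardScaler().fit(Xtr_a)
        sb = StandardScaler().fit(Xtr_b)
        assert np.array_equal(sa.mean_, sb.mean_) and np.array_equal(sa.scale_, sb.scale_)
        Xa, ya = smote(sa.transform(Xtr_a), ytr_a, SmoteConfig(seed=5))
        Xb, yb = smote(sb.transform(Xtr_b), ytr_b, SmoteConfig(seed=5))
        assert np.array_equal(Xa, Xb) and np.array_equal(ya, yb)


class TestSvrRegression:
    def test_noiseless_linear_relation_recovered(self):
        data, _ = _toy_data(8, per_subject=20, seed=6)
        score = 2.0 + 1.5 * data["f0"].to_numpy()
        # generous C: the noiseless target spans several units, so the
        # default epsilon-tube needs a weak-regularization regime
        r2, rmse = svr_regression_eval(data, score, ["f0"], C=100.0)
        assert r2 > 0.95
        assert rmse < 0.2
        assert rmse < np.std(score)  # beats the constant predictor

    def test_shuffled_scores_have_no_skill(self):
        rng = np.random.default_rng(7)
        data, _ = _toy_data(8, per_subject=20, seed=7)
        score = rng.permutation(2.0 + 1.5 * data["f0"].to_numpy())
        r2, _ = svr_regression_eval(data, score, FEATS)
        assert r2 <= 0.05
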