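"""LOOCV, confusion matrices, and the performance-statistic arithmetic."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lamegait.ranking import RankingConfig
from lamegait.synthetic import StudyConfig
from lamegait.validation import (
    AnalysisConfig,
    ConfusionMatrix,
    loocv,
    pct,
    performance,
    prediction_accuracy,
    run_analysis,
)


def matrix_from(counts, classes=None):
    counts = np.asarray(counts)
    if classes is None:
        classes = [f"c{i}" for i in range(counts.shape[0])]
    return ConfusionMatrix(classes=classes, counts=counts)


def feature_frame(X, y):
    df = pd.DataFrame(np.atleast_2d(X).T if np.ndim(X) == 1 else X)
    df.columns = [f"f{i}" for i in range(df.shape[1])]
    df["behaviour"] = y
    return df


class TestLoocv:
    def test_perfectly_separated_classes_give_diagonal_matrix(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10)])
        y = np.array(["a"] * 10 + ["b"] * 10)
        cm = loocv(feature_frame(X, y), ["f0"])
        np.testing.assert_array_equal(cm.counts, np.diag([10, 10]))

    def test_total_count_equals_row_count(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = np.array(["a", "b", "c"] * 10)
        cm = loocv(feature_frame(X, y), ["f0", "f1"])
        assert cm.total == 30

    def test_matches_independent_refit_oracle(self):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
        from sklearn.model_selection import LeaveOneOut

        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [5, 0], [0, 5]])
        X = np.vstack([c + rng.normal(0, 1.0, (5, 2)) for c in centers])
        y = np.repeat(["a", "b", "c"], 5)
        cm = loocv(feature_frame(X, y), ["f0", "f1"], shrinkage=1e-12)
        oracle = np.zeros((3, 3), dtype=int)
        idx = {c: i for i, c in enumerate(["a", "b", "c"])}
        for train, test in LeaveOneOut().split(X):
            q = QuadraticDiscriminantAnalysis(store_covariance=True)
            q.fit(X[train], y[train])
            pred = q.predict(X[test])[0]
            oracle[idx[pred], idx[y[test][0]]] += 1
        np.testing.assert_array_equal(cm.counts, oracle)

    def test_class_with_too_few_rows_aborts_with_fold_count(self):
        X = np.arange(7.0)
        y = np.array(["a"] * 5 + ["b"] * 2)
        with pytest.raises(ValueError, match="2 folds"):
            loocv(feature_frame(X, y), ["f0"])


class TestPredictionAccuracy:
    def test_reference_ear_lame_walking_column(self):
        from lamegait.datasets import reference_confusion_matrix

        cm = reference_confusion_matrix("ear", "II")
        acc = prediction_accuracy(cm, "lame_walking")
        assert acc == pytest.approx(80 / 98)
        assert pct(acc) == 82

    def test_reference_leg_sound_lying_column(self):
        from lamegait.datasets import reference_confusion_matrix

        cm = reference_confusion_matrix("leg", "II")
        assert prediction_accuracy(cm, "sound_lying") == 1.0

    def test_identity_matrix_is_perfect(self):
        cm = matrix_from(np.eye(4, dtype=int))
        for c in cm.classes:
            assert prediction_accuracy(cm, c) == 1.0

    def test_empty_observed_column_reported_missing(self):
        cm = matrix_from([[3, 0], [2, 0]])
        assert prediction_accuracy(cm, "c1") is None


class TestPerformance:
    def test_one_vs_rest_counts_and_metrics(self):
        cm = matrix_from([[5, 2], [1, 7]])
        rep = performance(cm)
        p = rep.per_class["c0"]
        assert (p.tp, p.fn, p.fp, p.tn) == (5, 1, 2, 7)
        assert p.sensitivity == pytest.approx(5 / 6)
        assert p.specificity == pytest.approx(7 / 9)
        assert p.accuracy == pytest.approx(12 / 15)
        assert p.precision == pytest.approx(5 / 7)

    def test_perfect_diagonal_matrix_all_metrics_one(self):
        rep = performance(matrix_from(np.diag([4, 6, 8])))
        for c in rep.classes:
            p = rep.per_class[c]
            assert p.sensitivity == p.specificity == p.accuracy == p.precision == 1.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            performance(matrix_from(np.zeros((2, 2), dtype=int)))

    def test_zero_denominator_reported_missing(self):
        # nothing observed or predicted as c1
        rep = performance(matrix_from([[5, 0], [0, 0]]))
        p = rep.per_class["c1"]
        assert p.sensitivity is None and p.precision is None

    @given(st.integers(0, 2**31 - 1))
    def test_prediction_accuracy_equals_sensitivity(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(2, 6))
        counts = rng.integers(0, 50, size=(K, K))
        counts[0, 0] += 1  # non-empty
        cm = matrix_from(counts)
        rep = performance(cm)
        for c in cm.classes:
            assert rep.per_class[c].sensitivity == prediction_accuracy(cm, c)

    @given(st.integers(0, 2**31 - 1))
    def test_conservation_of_counts(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(4, 4))
        counts[1, 1] += 1
        cm = matrix_from(counts)
        rep = performance(cm)
        for i, c in enumerate(cm.classes):
            p = rep.per_class[c]
            assert p.tp + p.fp + p.fn + p.tn == cm.total
            assert p.tp + p.fn == cm.observed_total(c)
            assert p.tp + p.fp == cm.predicted_total(c)


def test_pct_rounds_half_up():
    assert pct(0.815) == 82
    assert pct(0.345) == 35  # 34.5 rounds up
    assert pct(0.5) == 50
    assert pct(None) is None


def small_analysis_config(seed=4, analysis="II"):
    counts = {"sound_grazing": 8, "sound_standing": 8, "sound_walking": 8,
              "lame_walking": 8}
    if analysis == "I":
        counts["lame_grazing"] = 8
    study = StudyConfig(animals=2, epoch_counts=counts, deployments=("ear",),
                        seed=seed)
    return AnalysisConfig(study=study, deployment="ear", analysis=analysis,
                          ranking=RankingConfig(ntree=30, seed=seed))


class TestRunAnalysis:
    def test_end_to_end_smoke_with_absent_class_dropped(self):
        with pytest.warns(RuntimeWarning, match="dropped"):
            rep = run_analysis(small_analysis_config())
        assert rep.dropped_classes == ["sound_lying"]
        assert len(rep.selected_features) == 3
        assert rep.confusion.total == 32  # epoch_counts are deployment totals
        assert set(rep.confusion.classes) == {"sound_grazing", "sound_standing",
                                              "sound_walking", "lame_walking"}

    def test_identical_config_and_seed_give_identical_report_bytes(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_analysis(small_analysis_config(seed=9)).to_json()
            b = run_analysis(small_analysis_config(seed=9)).to_json()
        assert a == b

    def test_confusion_matrix_csv_round_trip(self, tmp_path):
        cm = matrix_from([[5, 2], [1, 7]], classes=["sound_grazing",
                                                    "lame_walking"])
        path = tmp_path / "cm.csv"
        cm.to_csv(path)
        df = pd.read_csv(path, index_col=0)
        np.testing.assert_array_equal(df.to_numpy(), cm.counts)
        assert list(df.columns) == cm.classes
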