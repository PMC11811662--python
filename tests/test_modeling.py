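"""Selection, classifiers, fusion rules, and LOSO protocol."""

import numpy as np
import pytest

from painpipe.config import ModelConfig
from painpipe.modeling import (NonEvaluableFold, SubjectData, TaskSpec,
                               balanced_accuracy, confusion_counts,
                               early_fuse, gini_select, late_fuse,
                               loso_evaluate, train_classifier)
from painpipe.types import FeatureWindow, LabeledInstance


def fw(t_start, values, modality="ECG", subject="S1", wl=10.0):
    values = np.atleast_1d(np.asarray(values, float))
    return FeatureWindow(subject_id=subject, modality=modality,
                         t_start=t_start, t_end=t_start + wl, window_len=wl,
                         values=values,
                         names=[f"{modality.lower()}{i}" for i in range(values.size)])


class TestBalancedAccuracy:
    def test_perfect(self):
        y = np.array(["BL", "BL", "PL2", "PL2"])
        assert balanced_accuracy(y, y) == 1.0

    def test_all_positive_on_even_split(self):
        y = np.array(["BL", "BL", "PL2", "PL2"])
        assert balanced_accuracy(y, np.array(["PL2"] * 4)) == 0.5

    def test_hand_computed_confusion(self):
        y_true = np.array(["P"] * 10 + ["N"] * 10)
        y_pred = np.array(["P"] * 8 + ["N"] * 2 + ["P"] * 4 + ["N"] * 6)
        assert abs(balanced_accuracy(y_true, y_pred) - 0.7) < 1e-12
        assert confusion_counts(y_true, y_pred, "P") == (8, 4, 6, 2)

    def test_missing_class_non_evaluable(self):
        with pytest.raises(NonEvaluableFold):
            balanced_accuracy(np.array(["P", "P"]), np.array(["P", "N"]))


class TestGiniSelect:
    def test_planted_predictor_dominates(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = rng.integers(0, 2, size=120)
            X = rng.normal(size=(120, 30))
            X[:, 7] = y  # perfect predictor
            cols = gini_select(X, y, k=5, seed=seed)
            assert 7 in cols

    def test_fewer_columns_all_kept(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 20))
        y = rng.integers(0, 2, size=40)
        assert gini_select(X, y, k=25, seed=0).size == 20

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 40))
        y = rng.integers(0, 2, size=60)
        np.testing.assert_array_equal(gini_select(X, y, 25, seed=3),
                                      gini_select(X, y, 25, seed=3))

    def test_exactly_k_columns(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 111))
        y = rng.integers(0, 2, size=60)
        assert gini_select(X, y, 25, seed=0).size == 25


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["svm", "rf", "adaboost", "knn"])
    def test_separable_blobs_learned(self, kind):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, .4, (30, 2)), rng.normal(2, .4, (30, 2))])
        y = np.array(["BL"] * 30 + ["PL3"] * 30)
        model = train_classifier(kind, X, y, seed=0)
        assert balanced_accuracy(y, model.predict(X)) >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier("rf", np.zeros((5, 2)), np.array(["a"] * 5))

    def test_same_seed_same_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, size=50).astype(str)
        m1 = train_classifier("rf", X, y, seed=5)
        m2 = train_classifier("rf", X, y, seed=5)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


class TestEarlyFuse:
    def _sets(self, shift=0.0):
        sets = {}
        dims = {"ECG": 19, "EMG": 70, "EDA": 12, "RR": 10}
        for mod, d in dims.items():
            off = shift if mod == "RR" else 0.0
            sets[mod] = [fw(10.0 * i + off, np.zeros(d), mod) for i in range(5)]
        return sets

    def test_identical_grids_preserved(self):
        groups = early_fuse(self._sets(), align_tol_s=10.0)
        assert len(groups) == 5
        assert [w.modality for w in groups[0]] == ["ECG", "EMG", "EDA", "RR"]
        assert sum(w.values.size for w in groups[0]) == 111

    def test_shifted_modality_beyond_span_errors(self):
        with pytest.raises(ValueError):
            early_fuse(self._sets(shift=100.0), align_tol_s=10.0)

    def test_one_modality_rejected(self):
        with pytest.raises(ValueError):
            early_fuse({"ECG": self._sets()["ECG"]}, 10.0)


class TestLateFuse:
    def test_majority(self):
        assert late_fuse([("PL2", .6), ("PL2", .7), ("BL", .9), ("PL2", .5)]) == "PL2"

    def test_tie_broken_by_mean_confidence(self):
        votes = [("A", 0.8), ("A", 0.8), ("B", 0.6), ("B", 0.6)]
        assert late_fuse(votes) == "A"
        votes = [("A", 0.5), ("A", 0.5), ("B", 0.9), ("B", 0.9)]
        assert late_fuse(votes) == "B"

    def test_single_member(self):
        assert late_fuse([("PL1", 0.4)]) == "PL1"


def synthetic_subjects(n_subjects=5, n_per_class=8, sep=3.0, d=6, seed=0,
                       modality="ECG"):
    """Subjects whose BL/PL3 instances are Gaussian blobs sep apart."""
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(n_subjects):
        offset = rng.normal(0, 0.5, size=d)   # subject-specific baseline
        inst = []
        for label, center in (("BL", 0.0), ("PL3", sep)):
            for j in range(n_per_class):
                v = rng.normal(center, 1.0, size=d) + offset
                inst.append(LabeledInstance(
                    [fw(10.0 * j, v, modality, f"S{s}")], label, "strong"))
        subjects.append(SubjectData(f"S{s}", inst))
    return subjects


class TestLoso:
    def test_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            loso_evaluate(synthetic_subjects(2), TaskSpec("PL3"))

    def test_fold_count_and_separable_accuracy(self):
        subjects = synthetic_subjects(5)
        res, audit = loso_evaluate(subjects, TaskSpec("PL3", classifier="svm"),
                                   return_audit=True)
        assert len(res.per_fold) == 5
        assert res.mean > 0.9
        assert audit.leak_free

    def test_held_out_never_in_training(self):
        subjects = synthetic_subjects(4)
        _, audit = loso_evaluate(subjects, TaskSpec("PL3"), return_audit=True)
        for held, info in audit.folds.items():
            assert held not in info["train_subjects"]
            assert info["test_provenances"] == ["strong"]

    def test_mean_sd_recomputable_from_folds(self):
        subjects = synthetic_subjects(5, sep=1.0)
        res = loso_evaluate(subjects, TaskSpec("PL3", classifier="knn"))
        bas = [f.balanced_accuracy for f in res.per_fold]
        assert abs(res.mean - np.mean(bas)) < 1e-12
        assert abs(res.sd - np.std(bas, ddof=1)) < 1e-12

    def test_smote_augmentation_path(self):
        subjects = synthetic_subjects(4, n_per_class=6)
        # unbalance the classes by dropping some positives
        for s in subjects:
            s.strong = [i for i in s.strong if not
                        (i.label == "PL3" and i.windows[0].t_start > 20)]
        res = loso_evaluate(subjects,
                            TaskSpec("PL3", augmentation="smote"))
        assert len(res.per_fold) == 4

    def test_late_fusion_path(self):
        rng = np.random.default_rng(0)
        subjects = []
        for s in range(4):
            inst = []
            for label, center in (("BL", 0.0), ("PL3", 3.0)):
                for j in range(6):
                    wins = [fw(10.0 * j, rng.normal(center, 1, 4), m, f"S{s}")
                            for m in ("ECG", "RR")]
                    inst.append(LabeledInstance(wins, label, "strong"))
            subjects.append(SubjectData(f"S{s}", inst))
        res = loso_evaluate(subjects, TaskSpec("PL3", fusion="late",
                                               classifier="svm"))
        assert len(res.per_fold) == 4
        assert res.mean > 0.8
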