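"""Feature selection, classifiers, fusion, and LOSO evaluation.

The evaluation protocol is leave-one-subject-out (LOSO): each fold holds
out every instance of one subject, fits the entire chain — Gini-importance
feature selection, optional weak labeling, optional SMOTE, per-feature
standardization, classifier — on the remaining subjects only, and scores
balanced accuracy ((TPR + TNR)/2) on the held-out subject's *strong*
labels.  Folds whose held-out subject lacks one of the two task classes
are non-evaluable and excluded from the mean/SD (configurable to score
0.5 instead).  An audit trail records which subjects each fitting step
saw, so leakage is checkable mechanically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .augment import SmoteConfig, smote_oversample
from .config import LabelsConfig, ModelConfig
from .labels import WindowGroup, weak_label
from .types import EvalResult, FoldResult, LabeledInstance

log = logging.getLogger("painpipe")

MODALITY_ORDER = ("ECG", "EMG", "EDA", "RR")


class NonEvaluableFold(RuntimeError):
    pass


@dataclass
class TaskSpec:
    """One binary pain-recognition task (BL vs one pain level)."""

    positive_class: str                  # PL1 | PL2 | PL3
    negative_class: str = "BL"
    classifier: str = "svm"              # svm | rf | adaboost | knn
    fusion: str = "none"                 # early | late | none
    augmentation: str = "none"           # none | smote | weak | both
    selection_k: int = 25

    @property
    def name(self) -> str:
        return f"{self.negative_class}_vs_{self.positive_class}"


# ------------------------------------------------------------- primitives

def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(TPR + TNR) / 2 for a binary problem; both classes must appear."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true)
    if classes.size != 2:
        raise NonEvaluableFold(
            f"need both classes in y_true, got {list(classes)}")
    rates = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(rates))


def confusion_counts(y_true, y_pred, positive) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    tn = int(np.sum(~pos & (y_pred != positive)))
    fp = int(np.sum(~pos & (y_pred == positive)))
    return tp, fp, tn, fn


def gini_select(X_train: np.ndarray, y_train: np.ndarray, k: int = 25,
                seed: int = 0) -> np.ndarray:
    """Indices of the top-k columns by random-forest Gini importance.

    Fit on the training fold only.  Returns all columns (with a warning)
    when fewer than k exist.  Ties break toward the lower column index,
    so the selection is deterministic given the seed.
    """
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("constant labels: importance undefined")
    if X_train.shape[1] <= k:
        if X_train.shape[1] < k:
            log.warning("only %d columns available; keeping all (k=%d)",
                        X_train.shape[1], k)
        return np.arange(X_train.shape[1])
    rf = RandomForestClassifier(n_estimators=100, random_state=seed)
    rf.fit(X_train, y_train)
    imp = rf.feature_importances_
    order = np.lexsort((np.arange(imp.size), -imp))
    return np.sort(order[:k])


def train_classifier(kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0,
                     cfg: ModelConfig | None = None):
    """Fit one of the four classifier kinds with documented defaults.

    SVM and k-NN sit behind a per-feature standardizer (fit here, i.e. on
    whatever training data is passed in); tree ensembles consume raw
    features.  All models expose predict and predict_proba.
    """
    cfg = cfg or ModelConfig()
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need >= 2 classes to train a classifier")
    if kind == "svm":
        clf = SVC(C=cfg.svm_c, gamma=cfg.svm_gamma, kernel="rbf",
                  random_state=seed)
        model = make_pipeline(StandardScaler(), clf) if cfg.standardize else clf
    elif kind == "rf":
        model = RandomForestClassifier(n_estimators=cfg.rf_n_estimators,
                                       random_state=seed)
    elif kind == "adaboost":
        model = AdaBoostClassifier(n_estimators=cfg.adaboost_n_estimators,
                                   random_state=seed)
    elif kind == "knn":
        knn = KNeighborsClassifier(n_neighbors=cfg.knn_k, weights="uniform")
        model = make_pipeline(StandardScaler(), knn) if cfg.standardize else knn
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    model.fit(np.asarray(X, float), y)
    return model


def predict_with_confidence(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels plus a confidence in [0, 1] per row.

    Uses calibratable class probabilities where the model provides them;
    margin-based models (SVM) fall back to a logistic squash of the
    decision function.
    """
    classes = model.classes_ if hasattr(model, "classes_") else model[-1].classes_
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        idx = np.argmax(proba, axis=1)
        return classes[idx], proba[np.arange(len(X)), idx]
    margin = np.asarray(model.decision_function(X), float)
    conf = 1.0 / (1.0 + np.exp(-np.abs(margin)))
    idx = (margin > 0).astype(int)
    return classes[idx], conf


# ----------------------------------------------------------------- fusion

def early_fuse(feature_sets: dict[str, list], align_tol_s: float,
               ) -> list[WindowGroup]:
    """Row-align windows across modalities by midpoint and concatenate.

    Each output group holds one window per modality, ordered ECG, EMG,
    EDA, RR; a row exists only where every modality has a window whose
    midpoint is within ``align_tol_s`` of the reference (first) modality's
    window midpoint.
    """
    mods = [m for m in MODALITY_ORDER if feature_sets.get(m)]
    if len(mods) < 2:
        raise ValueError("early fusion needs >= 2 modalities")
    ref = sorted(feature_sets[mods[0]], key=lambda w: w.midpoint)
    groups: list[WindowGroup] = []
    for w0 in ref:
        group = [w0]
        for m in mods[1:]:
            cands = feature_sets[m]
            best = min(cands, key=lambda w: abs(w.midpoint - w0.midpoint))
            if abs(best.midpoint - w0.midpoint) > align_tol_s:
                group = None
                break
            group.append(best)
        if group is not None:
            groups.append(group)
    if not groups:
        raise ValueError("no alignable rows across modalities")
    return groups


def late_fuse(votes: list[tuple[str, float]]) -> str:
    """Majority vote over per-modality (label, confidence) predictions.

    Ties break by highest mean confidence, then by input (modality)
    order.
    """
    if not votes:
        raise ValueError("no member predictions")
    labels = [v[0] for v in votes]
    uniq = list(dict.fromkeys(labels))          # preserves first-seen order
    counts = {u: labels.count(u) for u in uniq}
    top = max(counts.values())
    tied = [u for u in uniq if counts[u] == top]
    if len(tied) == 1:
        return tied[0]
    mean_conf = {u: float(np.mean([c for l, c in votes if l == u]))
                 for u in tied}
    best = max(mean_conf.values())
    for u in tied:                               # first-seen order on ties
        if mean_conf[u] == best:
            return u
    raise AssertionError("unreachable")


# ------------------------------------------------------------------- LOSO

@dataclass
class SubjectData:
    """One subject's labeled instances and leftover unlabeled windows."""

    subject_id: str
    strong: list[LabeledInstance]
    unlabeled: list[WindowGroup] = field(default_factory=list)


@dataclass
class LosoAudit:
    """Which subjects each fold's fitting routines were allowed to see."""

    folds: dict[str, dict] = field(default_factory=dict)

    def record(self, held_out: str, train_subjects: set[str],
               test_provenances: set[str]) -> None:
        self.folds[held_out] = {
            "train_subjects": sorted(train_subjects),
            "test_provenances": sorted(test_provenances),
            "leak": held_out in train_subjects,
        }

    @property
    def leak_free(self) -> bool:
        return all(not f["leak"] and set(f["test_provenances"]) == {"strong"}
                   for f in self.folds.values())


def _instance_matrix(instances: list[LabeledInstance],
                     modality: str | None = None) -> np.ndarray:
    if modality is None:
        return np.vstack([inst.vector for inst in instances])
    rows = []
    for inst in instances:
        vals = [w.values for w in inst.windows if w.modality == modality]
        rows.append(np.concatenate(vals))
    return np.vstack(rows)


def _fit_single(X, y, task: TaskSpec, cfg: ModelConfig, seed: int):
    cols = gini_select(X, y, task.selection_k, seed)
    Xs = X[:, cols]
    if task.augmentation in ("smote", "both"):
        Xs, y, _ = smote_oversample(Xs, y, SmoteConfig(seed=seed))
    model = train_classifier(task.classifier, Xs, y, seed, cfg)
    return cols, model


def loso_evaluate(subjects: list[SubjectData], task: TaskSpec,
                  model_cfg: ModelConfig | None = None,
                  labels_cfg: LabelsConfig | None = None,
                  seed: int = 0,
                  return_audit: bool = False):
    """Leave-one-subject-out evaluation of one binary task.

    Requires >= 3 subjects with strong labels in both task classes.  All
    fitting (weak labeling, selection, SMOTE, standardization, the
    classifier) happens on training-fold subjects only.
    """
    model_cfg = model_cfg or ModelConfig()
    labels_cfg = labels_cfg or LabelsConfig()
    wanted = {task.negative_class, task.positive_class}

    def task_strong(s: SubjectData) -> list[LabeledInstance]:
        return [i for i in s.strong if i.label in wanted]

    evaluable = [s for s in subjects
                 if {i.label for i in task_strong(s)} == wanted]
    if len(evaluable) < 3:
        raise ValueError(
            f"need >= 3 subjects with strong labels in both classes, "
            f"have {len(evaluable)}")

    audit = LosoAudit()
    folds: list[FoldResult] = []
    non_eval: list[str] = []
    for held in evaluable:
        train_subj = [s for s in subjects if s.subject_id != held.subject_id]
        train = [i for s in train_subj for i in task_strong(s)]
        if task.augmentation in ("weak", "both"):
            pool = [g for s in train_subj for g in s.unlabeled]
            weak = weak_label(train, pool, labels_cfg, seed)
            train = train + [i for i in weak if i.label in wanted]

        test = task_strong(held)
        y_train = np.array([i.label for i in train])
        y_test = np.array([i.label for i in test])
        audit.record(held.subject_id,
                     {i.windows[0].subject_id for i in train},
                     {i.provenance for i in test})

        if task.fusion == "late":
            mods = sorted({w.modality for w in test[0].windows},
                          key=MODALITY_ORDER.index)
            members = []
            for m in mods:
                Xm = _instance_matrix(train, m)
                members.append((m, *_fit_single(Xm, y_train.copy(), task,
                                                model_cfg, seed)))
            preds = []
            for inst in test:
                votes = []
                for m, cols, model in members:
                    xm = _instance_matrix([inst], m)[:, cols]
                    labs, confs = predict_with_confidence(model, xm)
                    votes.append((str(labs[0]), float(confs[0])))
                preds.append(late_fuse(votes))
            y_pred = np.array(preds)
        else:
            X_train = _instance_matrix(train)
            X_test = _instance_matrix(test)
            cols, model = _fit_single(X_train, y_train, task, model_cfg, seed)
            y_pred = model.predict(X_test[:, cols])

        try:
            ba = balanced_accuracy(y_test, y_pred)
        except NonEvaluableFold:
            if model_cfg.score_non_evaluable_as_half:
                ba = 0.5
            else:
                non_eval.append(held.subject_id)
                log.info("fold %s non-evaluable", held.subject_id)
                continue
        tp, fp, tn, fn = confusion_counts(y_test, y_pred, task.positive_class)
        folds.append(FoldResult(held.subject_id, tp, fp, tn, fn, ba))

    result = EvalResult.from_folds(task.name, folds, non_eval)
    return (result, audit) if return_audit else result
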