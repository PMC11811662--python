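"""Pain-class mapping, strong-label assignment, and weak supervision.

NRS self-reports (0–10) are downsampled to four classes: BL (baseline /
no pain), PL1 (NRS 1–3), PL2 (NRS 4–6), PL3 (NRS 7–10).  By default NRS 0
maps to BL so the binary tasks BL-vs-PLk have disjoint classes; the
literal mapping with PL1 covering 0–3 is available via
``strict_paper_ranges``.

A window receives a *strong* label when its midpoint lies within the
labeling threshold (5.5 s or 10 s, matching the window length) of an NRS
report, or inside a designated baseline span (→ BL).  Remaining windows
are unlabeled and may be filled in by the weak-supervision label model:
an RBF-kernel SVM, a random forest, and a uniform-weight k-NN are trained
on the strong labels, and each unlabeled instance takes the class of the
member whose maximum calibrated class-probability is largest (ties broken
by fixed member priority SVM > RF > KNN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import LabelsConfig
from .types import FeatureWindow, LabeledInstance, PainAnnotation

log = logging.getLogger("painpipe")

WindowGroup = list[FeatureWindow]


@dataclass(frozen=True)
class ClassMap:
    """NRS → {BL, PL1, PL2, PL3} with inclusive bounds."""

    strict_paper_ranges: bool = False

    def __call__(self, nrs: int) -> str:
        if not (0 <= nrs <= 10):
            raise ValueError(f"NRS out of range: {nrs}")
        if nrs == 0:
            return "PL1" if self.strict_paper_ranges else "BL"
        if nrs <= 3:
            return "PL1"
        if nrs <= 6:
            return "PL2"
        return "PL3"


def map_nrs_to_class(nrs: int, cmap: ClassMap | None = None) -> str:
    return (cmap or ClassMap())(nrs)


def _group_midpoint(group: WindowGroup) -> float:
    return float(np.mean([w.midpoint for w in group]))


def assign_strong_labels(
    groups: list[WindowGroup],
    annotations: list[PainAnnotation],
    threshold_s: float,
    baseline_spans: list[tuple[float, float]] | None = None,
    cmap: ClassMap | None = None,
) -> tuple[list[LabeledInstance], list[WindowGroup]]:
    """Attach ground-truth labels to windows near an NRS report.

    A window group is labeled with the class of the nearest annotation if
    its midpoint is within ``threshold_s`` of it; two equidistant
    annotations that disagree discard the group (logged).  Midpoints
    inside a baseline span map to BL.  Returns (labeled, unlabeled).
    """
    cmap = cmap or ClassMap()
    spans = baseline_spans or []
    ann_t = np.array([a.t for a in annotations])
    labeled: list[LabeledInstance] = []
    unlabeled: list[WindowGroup] = []

    for group in groups:
        mid = _group_midpoint(group)
        if any(a <= mid <= b for a, b in spans):
            labeled.append(LabeledInstance(group, "BL", "strong"))
            continue
        if ann_t.size == 0:
            unlabeled.append(group)
            continue
        dist = np.abs(ann_t - mid)
        dmin = dist.min()
        if dmin > threshold_s:
            unlabeled.append(group)
            continue
        nearest = [annotations[i] for i in np.flatnonzero(dist == dmin)]
        classes = {cmap(a.nrs) for a in nearest}
        if len(classes) > 1:
            log.info("window at t=%.1f discarded: equidistant annotations "
                     "with conflicting classes %s", mid, sorted(classes))
            continue
        labeled.append(LabeledInstance(group, classes.pop(), "strong"))
    return labeled, unlabeled


def _label_model_members(cfg: LabelsConfig, seed: int):
    svm = make_pipeline(
        StandardScaler(),
        CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                               method="sigmoid", cv=3))
    rf = RandomForestClassifier(random_state=seed)
    knn = make_pipeline(StandardScaler(),
                        KNeighborsClassifier(n_neighbors=cfg.knn_k,
                                             weights="uniform"))
    return [("SVM", svm), ("RF", rf), ("KNN", knn)]  # tie-break priority order


def most_confident(member_preds: list[tuple[str, float]]) -> str:
    """Combination rule of the label model: the prediction of the member
    with the largest class-probability wins; ties keep the earlier
    (higher-priority) member."""
    if not member_preds:
        raise ValueError("no member predictions")
    best = None
    for rank, (lab, conf) in enumerate(member_preds):
        if best is None or conf > best[0]:
            best = (conf, rank, lab)
    return best[2]


def weak_label(strong: list[LabeledInstance], unlabeled: list[WindowGroup],
               cfg: LabelsConfig | None = None,
               seed: int = 0) -> list[LabeledInstance]:
    """Label the unlabeled windows with the most confident member model.

    Skips (returning ``[]``) when the strong set has fewer than 2 classes
    or fewer than ``weak_min_per_class`` instances in some class.
    """
    cfg = cfg or LabelsConfig()
    if not unlabeled:
        return []
    y = np.array([inst.label for inst in strong])
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < cfg.weak_min_per_class:
        log.warning("weak labeling skipped: strong set degenerate "
                    "(classes=%s counts=%s)", list(classes), list(counts))
        return []
    X = np.vstack([inst.vector for inst in strong])
    Xu = np.vstack([np.concatenate([w.values for w in g]) for g in unlabeled])

    member_proba = []
    for _, model in _label_model_members(cfg, seed):
        model.fit(X, y)
        proba = model.predict_proba(Xu)
        member_proba.append((model, proba))

    out: list[LabeledInstance] = []
    model_classes = [m.classes_ if hasattr(m, "classes_") else m[-1].classes_
                     for m, _ in member_proba]
    for i, group in enumerate(unlabeled):
        member_preds = [(str(cls[int(np.argmax(proba[i]))]), float(proba[i].max()))
                        for (_, proba), cls in zip(member_proba, model_classes)]
        out.append(LabeledInstance(group, most_confident(member_preds), "weak"))
    return out


def label_dataset(groups: list[WindowGroup],
                  annotations: list[PainAnnotation],
                  baseline_spans: list[tuple[float, float]],
                  cfg: LabelsConfig | None = None,
                  seed: int = 0) -> tuple[list[LabeledInstance], list[WindowGroup]]:
    """Strong labels first; weak labels appended if enabled.

    Returns (instances, still_unlabeled).  Evaluation downstream must use
    only provenance == "strong" instances.
    """
    cfg = cfg or LabelsConfig()
    cmap = ClassMap(cfg.strict_paper_ranges)
    strong, unlabeled = assign_strong_labels(
        groups, annotations, cfg.threshold_s, baseline_spans, cmap)
    instances = list(strong)
    if cfg.weak_enabled:
        weak = weak_label(strong, unlabeled, cfg, seed)
        instances.extend(weak)
        unlabeled = [] if weak else unlabeled
    return instances, unlabeled
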