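"""Sparse-label handling: strong labels, weak supervision, SMOTE.

Windows within the labeling threshold of an NRS report (or inside a
baseline span) get strong labels; a three-model label model (SVM, RF,
KNN; most confident member wins) fills in the rest; SMOTE balances the
training classes by interpolating minority samples.
"""

from collections import Counter

import numpy as np

from painpipe import (CohortSpec, PipelineConfig, SmoteConfig,
                      generate_subject, smote_oversample, weak_label)
from painpipe.pipeline import build_subject_data

cfg = PipelineConfig().validate()
# the default minimum of 10 strong instances per class suits full cohorts;
# relax it for this single-subject demo so the label model actually runs
cfg.labels.weak_min_per_class = 3
rec, _ = generate_subject(
    CohortSpec(n_subjects=1, duration_s=300, n_activity_segments=4, seed=3),
    subject_seed=19)
data = build_subject_data(rec, cfg, modalities=["ECG"])
print("strong labels:", dict(Counter(i.label for i in data.strong)))
print("unlabeled windows:", len(data.unlabeled))

weak = weak_label(data.strong, data.unlabeled, cfg.labels, seed=0)
print("weak labels assigned:", dict(Counter(i.label for i in weak)))

X = np.vstack([i.vector for i in data.strong])
y = np.array([i.label for i in data.strong])
Xo, yo, prov = smote_oversample(X, y, SmoteConfig(seed=0))
print("class counts before SMOTE:", dict(Counter(y)))
print("class counts after SMOTE: ", dict(Counter(yo)),
      f"({int(np.sum(prov == 'smote'))} synthetic rows)")
# Evaluation downstream always uses strong labels only; weak and SMOTE
# instances exist purely to enlarge the training folds.
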