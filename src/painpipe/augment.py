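"""Synthetic minority oversampling (SMOTE).

Each synthetic sample is drawn on the segment between a randomly chosen
minority instance and one of its k nearest minority-class neighbors:
``x_new = x_i + u * (x_nn - x_i)`` with ``u ~ U[0, 1]``.  Neighbor search
uses Euclidean distance after per-feature standardization (fit on the
data being oversampled, i.e. the training fold); synthesis happens in the
original feature space.  Original rows are preserved verbatim, and class
counts are equalized to the majority count by default.

SMOTE must only ever be applied inside a training fold, after the
train/test split — never to evaluation data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger("painpipe")


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    ratio: float = 1.0          # 1.0 -> equalize to majority count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (0 < self.ratio <= 1.0):
            raise ValueError("ratio must be in (0, 1]")


def smote_oversample(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample minority classes; returns (X', y', provenance).

    ``provenance`` is ``"original"`` for the input rows (preserved
    verbatim, in order) and ``"smote"`` for appended synthetic rows.
    """
    cfg = cfg or SmoteConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need >= 2 classes for SMOTE")
    target = int(round(counts.max() * cfg.ratio))
    rng = np.random.default_rng(cfg.seed)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd          # standardized view for neighbor search only

    new_rows, new_labels = [], []
    for cls, count in zip(classes, counts):
        deficit = target - count
        if deficit <= 0:
            continue
        if count < 2:
            raise ValueError(
                f"minority class {cls!r} has {count} instance(s); need >= 2")
        k = cfg.k_neighbors
        if k >= count:
            k = count - 1
            log.warning("SMOTE k reduced to %d for class %r (%d instances)",
                        k, cls, count)
        idx = np.flatnonzero(y == cls)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xs[idx])
        _, nbr = nn.kneighbors(Xs[idx])      # col 0 is the point itself
        for _ in range(deficit):
            i = rng.integers(count)
            j = idx[nbr[i, 1 + rng.integers(k)]]
            u = rng.uniform()
            new_rows.append(X[idx[i]] + u * (X[j] - X[idx[i]]))
            new_labels.append(cls)

    if not new_rows:
        return X, y, np.array(["original"] * len(y))
    Xout = np.vstack([X, np.array(new_rows)])
    yout = np.concatenate([y, np.array(new_labels)])
    prov = np.array(["original"] * len(y) + ["smote"] * len(new_labels))
    return Xout, yout, prov
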