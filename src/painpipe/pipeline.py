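"""End-to-end orchestration: cohort → features → labels → LOSO results.

Convenience layer used by the CLI, the examples, and the evaluation
scripts.  It wires together preprocessing, handcrafted or autoencoder
feature extraction, fusion, labeling, and leave-one-subject-out
evaluation, while keeping every fitting step inside the training fold.
"""

from __future__ import annotations

import logging

import numpy as np

from .autoencode import (AEConfig, Autoencoder, TrainedEncoder,
                         extract_auto_features, normalize_windows, train_ae)
from .config import PipelineConfig
from .features import derive_respiration, extract_handcrafted, sliding_windows
from .labels import assign_strong_labels, ClassMap
from .modeling import (LosoAudit, SubjectData, TaskSpec, _fit_single,
                       _instance_matrix, balanced_accuracy, confusion_counts,
                       early_fuse, loso_evaluate)
from .preprocess import preprocess_recording
from .types import EvalResult, FeatureWindow, FoldResult, Recording

log = logging.getLogger("painpipe")


def windows_to_groups(windows: list[FeatureWindow],
                      modalities: list[str],
                      align_tol_s: float) -> list[list[FeatureWindow]]:
    """Group windows per timestamp: singletons for one modality, fused rows
    for several."""
    by_mod = {m: [w for w in windows if w.modality == m] for m in modalities}
    present = [m for m in modalities if by_mod[m]]
    if not present:
        return []
    if len(present) == 1:
        return [[w] for w in sorted(by_mod[present[0]], key=lambda w: w.t_start)]
    return early_fuse({m: by_mod[m] for m in present}, align_tol_s)


def build_subject_data(rec: Recording, cfg: PipelineConfig,
                       modalities: list[str] | None = None,
                       preprocessed: bool = False) -> SubjectData:
    """Handcrafted-feature SubjectData for one recording.

    Only strong labels are assigned here; weak labeling is applied inside
    each LOSO training fold.
    """
    modalities = modalities or ["ECG", "EMG", "EDA", "RR"]
    # only the raw channels backing the requested modalities are processed
    raw_needed = {("PPG" if m == "RR" else m) for m in modalities}
    rec_sub = Recording(rec.subject_id,
                        {m: ch for m, ch in rec.channels.items()
                         if m in raw_needed},
                        list(rec.annotations), list(rec.baseline_spans))
    pre = rec_sub if preprocessed else preprocess_recording(rec_sub, cfg.preprocess)
    windows = extract_handcrafted(pre, cfg.features.window_len, cfg.features)
    groups = windows_to_groups(windows, modalities, cfg.fusion.align_tol_s
                               or cfg.features.window_len)
    strong, unlabeled = assign_strong_labels(
        groups, rec.annotations, cfg.labels.threshold_s, rec.baseline_spans,
        ClassMap(cfg.labels.strict_paper_ranges))
    return SubjectData(rec.subject_id, strong, unlabeled)


def evaluate_cohort(recordings: list[Recording], cfg: PipelineConfig,
                    task: TaskSpec, modalities: list[str] | None = None,
                    seed: int | None = None, return_audit: bool = False):
    """Preprocess, extract, label and LOSO-evaluate one task."""
    subjects = [build_subject_data(r, cfg, modalities) for r in recordings]
    return loso_evaluate(subjects, task, cfg.model, cfg.labels,
                         seed=cfg.seeds.master if seed is None else seed,
                         return_audit=return_audit)


# ------------------------------------------------- autoencoder features

def _decimate(sig, target_fs: float | None):
    """Linear-interpolation decimation of a channel for autoencoder input."""
    from .types import Signal
    if target_fs is None or sig.fs <= target_fs:
        return sig
    n_out = int(round(sig.samples.size * target_fs / sig.fs))
    t_out = np.arange(n_out) / target_fs
    y = np.interp(t_out, np.arange(sig.samples.size) / sig.fs, sig.samples)
    return Signal(y, target_fs, sig.t0, sig.name)


def raw_modality_windows(rec: Recording, modality: str, window_len: float,
                         input_fs: float | None = None
                         ) -> tuple[list[np.ndarray], list[float]]:
    """Raw (preprocessed) signal windows for autoencoder input.

    For EMG returns one matrix per channel (list of 5); for other
    modalities a single-element list.  RR uses the PPG-derived
    respiration signal.  Channels faster than ``input_fs`` are decimated
    to it first (autoencoder inputs only; handcrafted features always see
    the native rate).
    """
    if modality == "RR":
        sig = derive_respiration(rec.channels["PPG"][0])
        chans = [sig]
    else:
        chans = rec.channels[modality]
    chans = [_decimate(c, input_fs) for c in chans]
    mats, t_starts = [], None
    for ch in chans:
        wins = sliding_windows(ch, window_len)
        t_starts = [t for t, _ in wins]
        mats.append(np.vstack([w for _, w in wins]) if wins else
                    np.empty((0, int(round(window_len * ch.fs)))))
    return mats, t_starts or []


def fit_modality_encoders(train_mats: list[np.ndarray], modality: str,
                          arch: str, cfg: PipelineConfig,
                          seed: int = 0) -> list[TrainedEncoder]:
    """Train one AE per channel matrix (5 for EMG, 1 otherwise)."""
    acfg = cfg.autoencoder
    latent = (acfg.emg_latent_per_channel if modality == "EMG"
              and not acfg.emg_single_ae else acfg.latent_dim)
    encoders = []
    for c, mat in enumerate(train_mats):
        ae_cfg = AEConfig(input_len=mat.shape[1], latent_dim=latent,
                          epochs=acfg.epochs, batch_size=acfg.batch_size,
                          learning_rate=acfg.learning_rate, arch=arch,
                          seed=seed + c)
        model = Autoencoder(ae_cfg)
        norm = normalize_windows(mat, acfg.normalization)
        encoders.append(train_ae(model, norm, ae_cfg, modality))
    return encoders


def encode_subject(encoders: list[TrainedEncoder], mats: list[np.ndarray],
                   t_starts: list[float], rec: Recording, modality: str,
                   window_len: float, norm: str) -> list[FeatureWindow]:
    """Encode one subject's windows; EMG channels concatenate to 30 dims."""
    per_chan = [enc.encode(normalize_windows(m, norm))
                for enc, m in zip(encoders, mats)]
    latents = np.hstack(per_chan)
    arch = encoders[0].arch
    names = [f"{arch}_{i}" for i in range(latents.shape[1])]
    return [FeatureWindow(subject_id=rec.subject_id, modality=modality,
                          t_start=t0, t_end=t0 + window_len,
                          window_len=window_len, values=z, names=names,
                          feature_source=f"auto_{arch}")
            for t0, z in zip(t_starts, latents)]


def loso_evaluate_auto(recordings: list[Recording], cfg: PipelineConfig,
                       task: TaskSpec, modality: str, arch: str = "cnn",
                       seed: int = 0, return_audit: bool = False):
    """LOSO evaluation on autoencoder features, AEs fit per training fold.

    Per fold the modality's autoencoder(s) are trained only on the
    training subjects' windows, then both sides are encoded — the
    held-out subject's windows pass through the trained encoder but never
    influence its weights.
    """
    wl = cfg.features.window_len
    pre = [preprocess_recording(r, cfg.preprocess) for r in recordings]
    per_subject = {r.subject_id: raw_modality_windows(
        r, modality, wl, cfg.autoencoder.input_fs) for r in pre}

    def subject_data(r: Recording, encs) -> SubjectData:
        mats, t0s = per_subject[r.subject_id]
        fw = encode_subject(encs, mats, t0s, r, modality, wl,
                            cfg.autoencoder.normalization)
        groups = [[w] for w in fw]
        strong, unlabeled = assign_strong_labels(
            groups, r.annotations, cfg.labels.threshold_s, r.baseline_spans,
            ClassMap(cfg.labels.strict_paper_ranges))
        return SubjectData(r.subject_id, strong, unlabeled)

    wanted = {task.negative_class, task.positive_class}
    audit = LosoAudit()
    folds: list[FoldResult] = []
    non_eval: list[str] = []
    for held in pre:
        train_recs = [r for r in pre if r.subject_id != held.subject_id]
        n_chan = len(per_subject[held.subject_id][0])
        train_mats = [np.vstack([per_subject[r.subject_id][0][c]
                                 for r in train_recs])
                      for c in range(n_chan)]
        encs = fit_modality_encoders(train_mats, modality, arch, cfg, seed)

        train_inst = [i for r in train_recs
                      for i in subject_data(r, encs).strong
                      if i.label in wanted]
        test_data = subject_data(held, encs)
        test_inst = [i for i in test_data.strong if i.label in wanted]
        y_test = np.array([i.label for i in test_inst])
        if set(y_test) != wanted:
            non_eval.append(held.subject_id)
            continue
        y_train = np.array([i.label for i in train_inst])
        audit.record(held.subject_id,
                     {i.windows[0].subject_id for i in train_inst},
                     {i.provenance for i in test_inst})
        X_train = _instance_matrix(train_inst)
        X_test = _instance_matrix(test_inst)
        cols, model = _fit_single(X_train, y_train, task, cfg.model, seed)
        y_pred = model.predict(X_test[:, cols])
        ba = balanced_accuracy(y_test, y_pred)
        tp, fp, tn, fn = confusion_counts(y_test, y_pred, task.positive_class)
        folds.append(FoldResult(held.subject_id, tp, fp, tn, fn, ba))

    result = EvalResult.from_folds(task.name, folds, non_eval)
    return (result, audit) if return_audit else result
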