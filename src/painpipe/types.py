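"""Core domain types shared across the pipeline.

A :class:`Recording` bundles one subject's multichannel biosignals (ECG,
EMG, EDA, PPG) with sparse NRS pain annotations and designated baseline
spans.  Downstream stages operate on :class:`FeatureWindow` objects — one
feature vector per time window per modality — and on
:class:`LabeledInstance` objects carrying a pain class and its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MODALITIES = ("ECG", "EMG", "EDA", "PPG")
#: Default channel counts per modality (1 ECG, 5 facial EMG, 1 EDA, 1 PPG).
DEFAULT_CHANNEL_SCHEMA = {"ECG": 1, "EMG": 5, "EDA": 1, "PPG": 1}

CLASSES = ("BL", "PL1", "PL2", "PL3")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class FormatError(ValueError):
    """Raised when an on-disk artifact is malformed or incomplete."""


@dataclass
class Signal:
    """A uniformly sampled channel.

    Parameters
    ----------
    samples : array of float
        Signal values in modality-specific units.
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Start time in seconds on the recording clock.
    name : str
        Channel identifier, e.g. ``"ecg"`` or ``"emg3"``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"channel {self.name!r} contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def copy_with(self, samples: np.ndarray, name: str | None = None) -> "Signal":
        return Signal(samples=np.asarray(samples, float), fs=self.fs, t0=self.t0,
                      name=self.name if name is None else name)


@dataclass(frozen=True)
class PainAnnotation:
    """A self-reported pain score on the 11-point numerical rating scale."""

    t: float
    nrs: int

    def __post_init__(self) -> None:
        if not (0 <= int(self.nrs) <= 10):
            raise ValidationError(f"NRS must be in 0..10, got {self.nrs}")


@dataclass
class Recording:
    """One subject's multichannel session plus annotations.

    ``channels`` maps modality name → list of :class:`Signal`; all channels
    of one modality must share a sampling rate.  ``baseline_spans`` are
    rest periods with no pain-inducing activity, used to anchor the BL
    (no-pain) class.
    """

    subject_id: str
    channels: dict[str, list[Signal]]
    annotations: list[PainAnnotation] = field(default_factory=list)
    baseline_spans: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mod, sigs in self.channels.items():
            if not sigs:
                raise ValidationError(f"modality {mod} has no channels")
            fs0 = sigs[0].fs
            if any(s.fs != fs0 for s in sigs):
                raise ValidationError(f"channels of {mod} have mixed sampling rates")
        self.annotations = sorted(self.annotations, key=lambda a: a.t)
        spans = sorted(self.baseline_spans)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValidationError("baseline_spans overlap")
        self.baseline_spans = spans

    def validate_schema(self, schema: dict[str, int] | None = None) -> None:
        """Check channel counts against a schema (default: the study's)."""
        schema = schema or DEFAULT_CHANNEL_SCHEMA
        for mod, n in schema.items():
            got = len(self.channels.get(mod, []))
            if got != n:
                raise ValidationError(
                    f"modality {mod}: expected {n} channel(s), found {got}")

    def fs(self, modality: str) -> float:
        return self.channels[modality][0].fs

    def duration(self) -> float:
        return max(s.duration for sigs in self.channels.values() for s in sigs)


@dataclass
class FeatureWindow:
    """One window's feature vector for one modality."""

    subject_id: str
    modality: str
    t_start: float
    t_end: float
    window_len: float
    values: np.ndarray
    names: list[str]
    feature_source: str = "handcrafted"  # handcrafted | auto_cnn | auto_lstm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != len(self.names):
            raise ValidationError(
                f"{self.values.size} values but {len(self.names)} names")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class LabeledInstance:
    """A (possibly fused) feature vector with a pain class and provenance."""

    windows: list[FeatureWindow]
    label: str
    provenance: str  # strong | weak | smote

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValidationError(f"unknown class {self.label!r}")
        if self.provenance not in ("strong", "weak", "smote"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([w.values for w in self.windows])

    @property
    def midpoint(self) -> float:
        return float(np.mean([w.midpoint for w in self.windows]))


@dataclass
class FoldResult:
    """Confusion counts and balanced accuracy for one held-out subject."""

    held_out_subject: str
    tp: int
    fp: int
    tn: int
    fn: int
    balanced_accuracy: float


@dataclass
class EvalResult:
    """Leave-one-subject-out evaluation summary."""

    task: str
    per_fold: list[FoldResult]
    mean: float
    sd: float
    non_evaluable: list[str] = field(default_factory=list)

    @staticmethod
    def from_folds(task: str, folds: Sequence[FoldResult],
                   non_evaluable: Sequence[str] = ()) -> "EvalResult":
        bas = [f.balanced_accuracy for f in folds]
        mean = float(np.mean(bas)) if bas else float("nan")
        sd = float(np.std(bas, ddof=1)) if len(bas) > 1 else 0.0
        return EvalResult(task=task, per_fold=list(folds), mean=mean, sd=sd,
                          non_evaluable=list(non_evaluable))
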