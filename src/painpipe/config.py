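"""Pipeline configuration: documented defaults plus YAML overrides.

Every stage of the pipeline reads its knobs from a :class:`PipelineConfig`.
The defaults encode the study protocol where it is stated (window lengths
5.5 s / 10 s, labeling threshold equal to the window length, autoencoder
epochs/batch/learning rate, four-class label map) and documented choices
where it is not (filter orders, cutoffs, classifier hyperparameters).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

log = logging.getLogger("painpipe")

ALLOWED_WINDOW_LENS = (5.5, 10.0)


class ConfigError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    ecg_band: tuple[float, float] = (0.1, 250.0)   # upper edge clamped to 0.45*fs
    ecg_order: int = 4
    emg_highpass_hz: float = 20.0
    emg_notch_hz: tuple[float, ...] = (50.0, 100.0)
    emg_order: int = 4
    notch_q: float = 30.0
    eda_ma_window_s: float = 1.0
    eda_lowpass_hz: float = 1.0
    eda_order: int = 4
    ppg_band: tuple[float, float] = (0.4, 8.0)
    ppg_order: int = 4
    ppg_ma_window_s: float = 0.25


@dataclass
class FeaturesConfig:
    window_len: float = 10.0
    step_s: float | None = None          # None -> non-overlapping (= window_len)
    allow_any_window_len: bool = False
    emg_p2p_subframe_s: float = 0.5
    inhale_prominence_frac: float = 0.2
    inhale_min_spacing_s: float = 1.5
    scr_peak_prominence: float = 0.01    # µS
    abs_nn_diff_extrema: bool = False    # signed min/max of NN diffs by default


@dataclass
class AutoencoderConfig:
    latent_dim: int = 32                 # ECG / EDA / RR
    emg_latent_per_channel: int = 6      # 5 channels -> 30 total
    epochs: int = 100
    batch_size: int = 10
    learning_rate: float = 1e-3
    normalization: str = "minmax"        # minmax | zscore
    emg_single_ae: bool = False          # one 30-latent AE instead of 5x6
    input_fs: float | None = 32.0        # decimate faster channels to this
                                         # rate before encoding (None = native)


@dataclass
class LabelsConfig:
    threshold_s: float = 10.0            # must match the window length used
    strict_paper_ranges: bool = False    # NRS 0 -> PL1 instead of BL
    weak_enabled: bool = False
    weak_min_per_class: int = 10
    knn_k: int = 5


@dataclass
class AugmentationConfig:
    smote_enabled: bool = False
    smote_k_neighbors: int = 5
    smote_ratio: float = 1.0             # 1.0 = equalize to majority


@dataclass
class ModelConfig:
    classifier: str = "svm"              # svm | rf | adaboost | knn
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    rf_n_estimators: int = 100
    adaboost_n_estimators: int = 50
    knn_k: int = 5
    standardize: bool = True             # scaler for svm/knn, fit on train fold
    score_non_evaluable_as_half: bool = False


@dataclass
class FusionConfig:
    mode: str = "none"                   # early | late | none
    align_tol_s: float | None = None     # None -> window length


@dataclass
class SelectionConfig:
    k: int = 25
    enabled: bool = True


@dataclass
class SeedsConfig:
    master: int = 0


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    labels: LabelsConfig = field(default_factory=LabelsConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seeds: SeedsConfig = field(default_factory=SeedsConfig)

    def validate(self) -> "PipelineConfig":
        if not self.features.allow_any_window_len and \
                self.features.window_len not in ALLOWED_WINDOW_LENS:
            raise ConfigError(
                f"features.window_len must be one of {ALLOWED_WINDOW_LENS} "
                "(set features.allow_any_window_len to override)")
        if self.features.step_s is None:
            self.features.step_s = self.features.window_len
        if self.fusion.align_tol_s is None:
            self.fusion.align_tol_s = self.features.window_len
        return self


def _apply_section(obj: Any, section: str, values: dict) -> None:
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, val in values.items():
        if key not in valid:
            raise ConfigError(
                f"unknown key {section}.{key}; valid keys: {sorted(valid)}")
        cur = getattr(obj, key)
        if isinstance(cur, tuple) and isinstance(val, (list, tuple)):
            val = tuple(val)
        setattr(obj, key, val)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Build a fully-resolved configuration from YAML plus overrides.

    An empty or missing file yields all defaults.  Unknown keys are an
    error that lists the valid alternatives.  A missing ``seeds`` section
    falls back to master seed 0 with a logged warning.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    if overrides:
        for sec, vals in overrides.items():
            raw.setdefault(sec, {}).update(vals)

    cfg = PipelineConfig()
    valid_sections = {f.name for f in dataclasses.fields(cfg)}
    for section, values in raw.items():
        if section not in valid_sections:
            raise ConfigError(
                f"unknown section {section!r}; valid sections: {sorted(valid_sections)}")
        if values is None:
            continue
        if not isinstance(values, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        _apply_section(getattr(cfg, section), section, values)

    if "seeds" not in raw:
        log.warning("no seeds section in config; using default master seed 0")
    return cfg.validate()


def config_to_dict(cfg: PipelineConfig) -> dict:
    return dataclasses.asdict(cfg)
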