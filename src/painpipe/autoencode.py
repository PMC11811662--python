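"""Automatic feature extraction with convolutional and LSTM autoencoders.

Each modality gets its own autoencoder trained unsupervised to minimize
reconstruction mean-squared error (Adam, learning rate 1e-3, batch size
10, 100 epochs by default).  The encoder's latent vector is the feature
vector: 32 dimensions for ECG, EDA and the derived respiration signal; 6
per EMG channel (5 channels → 30), for 126 automatic features across the
four modalities.

Architecture (convolutional variant): a linear layer first resamples the
window from its native length to the closest power of two (CP2), then
three strided 1-D convolutions (channels 16/32/64, kernel 3, stride 2)
halve the length three times, and a linear layer flattens to the latent
dimension.  The decoder mirrors this with three transposed convolutions
and a final linear layer back to the input length.  ReLU sits between
layers.  The LSTM variant runs a 64-unit LSTM over the window resampled
to CP2/8 steps and projects the last hidden state to the latent vector;
its decoder repeats the latent across CP2/8 steps through a second LSTM.

Encoders are trained on training-fold windows only so leave-one-subject-
out evaluation never sees the held-out subject during fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .types import FeatureWindow

LATENT_DEFAULT = 32
EMG_LATENT_PER_CHANNEL = 6


class ParameterError(ValueError):
    pass


def closest_power_of_two(n: int) -> int:
    """The power of two minimizing |n - 2^k|; ties break downward."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    k = max(0, int(np.floor(np.log2(n))))
    lo, hi = 2 ** k, 2 ** (k + 1)
    return lo if (n - lo) <= (hi - n) else hi


@dataclass
class AEConfig:
    input_len: int
    latent_dim: int = LATENT_DEFAULT
    epochs: int = 100
    batch_size: int = 10
    learning_rate: float = 1e-3
    arch: str = "cnn"            # cnn | lstm
    seed: int = 0
    cp2: int = field(init=False)

    def __post_init__(self) -> None:
        if self.input_len < 1:
            raise ParameterError("input_len must be >= 1")
        if self.latent_dim >= self.input_len:
            # a latent at least as wide as the raw window is no bottleneck
            raise ParameterError(
                f"latent_dim {self.latent_dim} must be < input_len "
                f"{self.input_len}")
        self.cp2 = max(8, closest_power_of_two(self.input_len))
        # low-rate channels (e.g. 4 Hz EDA) give windows shorter than the
        # latent budget; the first linear layer then upsamples to the
        # smallest power of two that keeps latent_dim < CP2
        while self.latent_dim >= self.cp2:
            self.cp2 *= 2
        if self.arch not in ("cnn", "lstm"):
            raise ParameterError(f"unknown arch {self.arch!r}")


def _resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation resampling as a fixed (n_in, n_out) matrix."""
    m = np.zeros((n_in, n_out))
    src = np.linspace(0, n_in - 1, n_out)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    for j in range(n_out):
        m[lo[j], j] += 1 - frac[j]
        m[hi[j], j] += frac[j]
    return m


class Autoencoder:
    """Encoder/decoder pair built from the numpy layer engine."""

    def __init__(self, cfg: AEConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        cp2 = cfg.cp2
        if cfg.arch == "cnn":
            flat = 64 * (cp2 // 8)
            self.encoder = nn.Sequential([
                nn.Dense(cfg.input_len, cp2, rng), nn.ReLU(),
                nn.Reshape((1, cp2)),
                nn.Conv1d(1, 16, rng), nn.ReLU(),
                nn.Conv1d(16, 32, rng), nn.ReLU(),
                nn.Conv1d(32, 64, rng), nn.ReLU(),
                nn.Reshape((flat,)),
                nn.Dense(flat, cfg.latent_dim, rng),
            ])
            self.decoder = nn.Sequential([
                nn.Dense(cfg.latent_dim, flat, rng), nn.ReLU(),
                nn.Reshape((64, cp2 // 8)),
                nn.ConvTranspose1d(64, 32, rng), nn.ReLU(),
                nn.ConvTranspose1d(32, 16, rng), nn.ReLU(),
                nn.ConvTranspose1d(16, 1, rng), nn.ReLU(),
                nn.Reshape((cp2,)),
                nn.Dense(cp2, cfg.input_len, rng),
            ])
        else:
            T = max(2, cp2 // 8)
            self._T = T
            hidden = 64
            self.encoder = nn.Sequential([
                nn.Dense(cfg.input_len, T, rng),      # resample to T steps
                nn.Reshape((T, 1)),
                nn.LSTM(1, hidden, rng),
                nn.TakeLast(),
                nn.Dense(hidden, cfg.latent_dim, rng),
            ])
            self.decoder = nn.Sequential([
                nn.RepeatSteps(T),
                nn.LSTM(cfg.latent_dim, hidden, rng),
                nn.TimeDistributed(nn.Dense(hidden, 1, rng)),
                nn.Reshape((T,)),
                nn.Dense(T, cfg.input_len, rng),
            ])

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def encode(self, x: np.ndarray) -> np.ndarray:
        return self.encoder.forward(np.atleast_2d(x))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encoder.forward(x))

    def backward(self, dy: np.ndarray) -> None:
        self.encoder.backward(self.decoder.backward(dy))

    def zero_grad(self) -> None:
        self.encoder.zero_grad()
        self.decoder.zero_grad()


def build_cnn_ae(cfg: AEConfig) -> Autoencoder:
    if cfg.arch != "cnn":
        raise ParameterError("config arch must be 'cnn'")
    return Autoencoder(cfg)


def build_lstm_ae(cfg: AEConfig) -> Autoencoder:
    if cfg.arch != "lstm":
        raise ParameterError("config arch must be 'lstm'")
    return Autoencoder(cfg)


def normalize_windows(w: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Per-window normalization prior to autoencoder training."""
    w = np.asarray(w, float)
    if method == "minmax":
        lo = w.min(axis=1, keepdims=True)
        rng = np.ptp(w, axis=1, keepdims=True)
        rng[rng == 0] = 1.0
        return (w - lo) / rng
    if method == "zscore":
        mu = w.mean(axis=1, keepdims=True)
        sd = w.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return (w - mu) / sd
    raise ParameterError(f"unknown normalization {method!r}")


@dataclass
class TrainedEncoder:
    arch: str
    modality: str
    model: Autoencoder
    loss_history: list[float]
    cfg: AEConfig

    def encode(self, windows: np.ndarray) -> np.ndarray:
        windows = np.atleast_2d(np.asarray(windows, float))
        if windows.shape[1] != self.cfg.input_len:
            raise ValueError(
                f"window length {windows.shape[1]} != training input_len "
                f"{self.cfg.input_len}")
        return self.model.encode(windows)


def train_ae(model: Autoencoder, windows: np.ndarray, cfg: AEConfig,
             modality: str = "") -> TrainedEncoder:
    """Train an autoencoder on normalized windows (N, input_len)."""
    windows = np.asarray(windows, float)
    if windows.ndim != 2 or windows.shape[1] != cfg.input_len:
        raise ParameterError("windows must be (N, input_len)")
    n = windows.shape[0]
    if n < cfg.batch_size:
        raise ParameterError(
            f"need >= batch_size ({cfg.batch_size}) windows, got {n}")

    rng = np.random.default_rng(cfg.seed + 1)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = windows[order[start:start + cfg.batch_size]]
            model.zero_grad()
            recon = model.forward(batch)
            loss, dgrad = nn.mse(recon, batch)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf reconstruction loss at epoch {len(history)}")
            model.backward(dgrad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedEncoder(arch=cfg.arch, modality=modality, model=model,
                          loss_history=history, cfg=cfg)


def extract_auto_features(enc: TrainedEncoder, windows: np.ndarray,
                          meta: list[dict] | None = None) -> list[FeatureWindow]:
    """Encode windows into per-window latent FeatureWindow objects.

    ``meta`` supplies subject_id / t_start / window_len per window; when
    omitted, placeholder metadata is used (pure matrix use).
    """
    latents = enc.encode(windows)
    names = [f"{enc.arch}_{i}" for i in range(latents.shape[1])]
    source = f"auto_{enc.arch}"
    out = []
    for i, z in enumerate(latents):
        m = meta[i] if meta else {}
        wl = float(m.get("window_len", 0.0))
        t0 = float(m.get("t_start", float(i)))
        out.append(FeatureWindow(
            subject_id=m.get("subject_id", ""), modality=m.get("modality", ""),
            t_start=t0, t_end=t0 + wl, window_len=wl,
            values=z, names=names, feature_source=source))
    return out


def save_encoder(enc: TrainedEncoder, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {"arch": enc.arch, "modality": enc.modality,
            "input_len": enc.cfg.input_len, "latent_dim": enc.cfg.latent_dim,
            "epochs": enc.cfg.epochs, "batch_size": enc.cfg.batch_size,
            "learning_rate": enc.cfg.learning_rate, "seed": enc.cfg.seed,
            "loss_history": enc.loss_history, "format_version": 1}
    (path / "encoder.json").write_text(json.dumps(meta, indent=2))
    arrays = {f"p{i}": p.value for i, p in enumerate(enc.model.params())}
    np.savez(path / "weights.npz", **arrays)


def load_encoder(path: str | Path) -> TrainedEncoder:
    path = Path(path)
    meta = json.loads((path / "encoder.json").read_text())
    cfg = AEConfig(input_len=meta["input_len"], latent_dim=meta["latent_dim"],
                   epochs=meta["epochs"], batch_size=meta["batch_size"],
                   learning_rate=meta["learning_rate"], arch=meta["arch"],
                   seed=meta["seed"])
    model = Autoencoder(cfg)
    data = np.load(path / "weights.npz")
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    return TrainedEncoder(arch=meta["arch"], modality=meta["modality"],
                          model=model, loss_history=meta["loss_history"],
                          cfg=cfg)
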