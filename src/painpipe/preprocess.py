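"""Modality-specific noise filtering.

All IIR filters are Butterworth designs applied zero-phase
(forward-backward with ``scipy.signal.filtfilt``), so the morphology and
timing of slow components — which downstream features depend on — are not
phase-shifted.  Per-modality pipelines:

* **ECG** — band-pass 0.1 Hz to min(250, 0.45·fs) Hz.  The nominal upper
  edge of 250 Hz collides with the Nyquist frequency at fs = 500 Hz, so it
  is clamped to 0.45·fs (225 Hz at 500 Hz) to keep the design stable.
* **EMG** — 20 Hz high-pass, then notch filters at 50 Hz and 100 Hz
  (powerline fundamental + harmonic).
* **EDA** — 1 s moving average (motion artifacts), then 1 Hz low-pass.
* **PPG** — band-pass 0.4–8 Hz (cardiac band plus its respiratory
  modulation), then a short moving-average smoother.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import PreprocessConfig
from .types import Recording, Signal


class FilterParameterError(ValueError):
    pass


@dataclass
class FilterSpec:
    kind: str                      # bandpass | highpass | lowpass | notch | moving_average
    cutoffs: tuple[float, ...] = ()
    order: int = 4
    q_factor: float = 30.0
    window_s: float = 1.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise FilterParameterError("filter order must be >= 1")


def _check_cutoffs(cutoffs: tuple[float, ...], fs: float) -> tuple[float, ...]:
    nyq = fs / 2.0
    out = []
    for c in cutoffs:
        if c <= 0:
            raise FilterParameterError(f"cutoff must be positive, got {c}")
        if c >= nyq:
            raise FilterParameterError(
                f"cutoff {c} Hz >= Nyquist {nyq} Hz at fs={fs}")
        out.append(c)
    return tuple(out)


def butterworth_filter(sig: Signal, spec: FilterSpec) -> Signal:
    """Zero-phase Butterworth filtering; same length and fs as the input."""
    if spec.kind not in ("bandpass", "highpass", "lowpass"):
        raise FilterParameterError(f"unsupported kind {spec.kind!r}")
    cutoffs = _check_cutoffs(spec.cutoffs, sig.fs)
    if spec.kind == "bandpass":
        if len(cutoffs) != 2 or cutoffs[0] >= cutoffs[1]:
            raise FilterParameterError("bandpass needs (low, high) with low < high")
        wn: float | tuple = cutoffs
    else:
        if len(cutoffs) != 1:
            raise FilterParameterError(f"{spec.kind} needs exactly one cutoff")
        wn = cutoffs[0]
    sos = sps.butter(spec.order, wn, btype=spec.kind, fs=sig.fs, output="sos")
    y = sps.sosfiltfilt(sos, sig.samples)
    return sig.copy_with(y)


def notch_filter(sig: Signal, f0: float, q: float = 30.0) -> Signal:
    """Zero-phase IIR notch at f0 Hz with quality factor q."""
    (f0,) = _check_cutoffs((f0,), sig.fs)
    b, a = sps.iirnotch(f0, q, fs=sig.fs)
    y = sps.filtfilt(b, a, sig.samples)
    return sig.copy_with(y)


def moving_average(sig: Signal, window_s: float) -> Signal:
    """Centered moving average; edges use shrunken windows (same length out)."""
    n = int(round(window_s * sig.fs))
    if n < 1:
        raise FilterParameterError("window shorter than one sample")
    if n > sig.samples.size:
        raise FilterParameterError("moving-average window longer than signal")
    # cumulative-sum sliding mean with edge windows truncated symmetrically
    x = sig.samples
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return sig.copy_with(num / den)


def ecg_clamped_band(band: tuple[float, float], fs: float) -> tuple[float, float]:
    lo, hi = band
    return lo, min(hi, 0.45 * fs)


def preprocess_modality(rec: Recording, modality: str,
                        cfg: PreprocessConfig | None = None) -> Recording:
    """Return a Recording with one modality's channels filtered."""
    cfg = cfg or PreprocessConfig()
    if modality not in rec.channels:
        raise KeyError(f"modality {modality!r} not present in recording")
    out = {m: list(sigs) for m, sigs in rec.channels.items()}
    filtered = [ _preprocess_channel(sig, modality, cfg)
                 for sig in rec.channels[modality] ]
    out[modality] = filtered
    return Recording(subject_id=rec.subject_id, channels=out,
                     annotations=list(rec.annotations),
                     baseline_spans=list(rec.baseline_spans))


def _preprocess_channel(sig: Signal, modality: str, cfg: PreprocessConfig) -> Signal:
    if modality == "ECG":
        band = ecg_clamped_band(cfg.ecg_band, sig.fs)
        return butterworth_filter(sig, FilterSpec("bandpass", band, cfg.ecg_order))
    if modality == "EMG":
        y = butterworth_filter(
            sig, FilterSpec("highpass", (cfg.emg_highpass_hz,), cfg.emg_order))
        for f0 in cfg.emg_notch_hz:
            if f0 < sig.fs / 2:
                y = notch_filter(y, f0, cfg.notch_q)
        return y
    if modality == "EDA":
        y = moving_average(sig, cfg.eda_ma_window_s)
        return butterworth_filter(
            y, FilterSpec("lowpass", (cfg.eda_lowpass_hz,), cfg.eda_order))
    if modality == "PPG":
        y = butterworth_filter(
            sig, FilterSpec("bandpass", cfg.ppg_band, cfg.ppg_order))
        return moving_average(y, cfg.ppg_ma_window_s)
    raise KeyError(f"unknown modality {modality!r}")


def preprocess_recording(rec: Recording,
                         cfg: PreprocessConfig | None = None) -> Recording:
    """Filter every modality present in the recording."""
    out = rec
    for modality in rec.channels:
        out = preprocess_modality(out, modality, cfg)
    return out
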