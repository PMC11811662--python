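"""QRS detection and NN-interval series.

The default detector is a deterministic Pan–Tompkins-style chain:
band-pass (5–15 Hz) → derivative → squaring → moving-window integration →
adaptive threshold, followed by refinement of each fiducial point to the
local maximum of the (preprocessed) ECG.  It sits behind the
:class:`PeakDetector` protocol so a learned detector can be swapped in.

A refractory period of 200 ms is enforced between accepted peaks, matching
the physiological lower bound on inter-beat intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import signal as sps

from .types import Signal

REFRACTORY_S = 0.2


class NoPeaksError(RuntimeError):
    """Fewer than two R-peaks found; HRV features cannot be computed."""


@dataclass
class NNSeries:
    """R-peak times (s) and the successive inter-beat intervals (ms)."""

    r_peak_times: np.ndarray
    nn_ms: np.ndarray

    def __post_init__(self) -> None:
        self.r_peak_times = np.asarray(self.r_peak_times, float)
        self.nn_ms = np.asarray(self.nn_ms, float)
        if np.any(self.nn_ms <= 0):
            raise ValueError("NN intervals must be positive")

    @staticmethod
    def from_times(times: np.ndarray) -> "NNSeries":
        times = np.asarray(times, float)
        if times.size < 2:
            raise NoPeaksError(f"need >= 2 peaks, got {times.size}")
        return NNSeries(times, np.diff(times) * 1000.0)


class PeakDetector(Protocol):
    def __call__(self, ecg: Signal) -> NNSeries: ...


def detect_r_peaks(ecg: Signal, refractory_s: float = REFRACTORY_S) -> NNSeries:
    """Pan–Tompkins-style R-peak detection on a preprocessed ECG signal."""
    x = ecg.samples
    fs = ecg.fs
    if x.size < int(fs):  # need at least ~1 s of signal
        raise NoPeaksError("signal too short for QRS detection")
    if np.ptp(x) == 0:
        raise NoPeaksError("flat signal: no QRS complexes")

    lo, hi = 5.0, min(15.0, 0.45 * fs)
    sos = sps.butter(2, (lo, hi), btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv ** 2
    win = max(1, int(round(0.15 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    # adaptive threshold: fraction of a robust running amplitude estimate
    thresh = 0.25 * np.quantile(integ, 0.98)
    min_dist = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(integ, height=thresh, distance=min_dist)
    if cand.size < 2:
        raise NoPeaksError("fewer than two QRS candidates above threshold")

    # refine each candidate to the local ECG maximum (R wave apex)
    half = max(1, int(round(0.075 * fs)))
    peaks = []
    for c in cand:
        a, b = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(a + int(np.argmax(x[a:b])))
    peaks = np.unique(peaks)

    # re-enforce refractory after refinement
    kept = [peaks[0]]
    for p in peaks[1:]:
        if p - kept[-1] >= min_dist:
            kept.append(p)
        elif x[p] > x[kept[-1]]:
            kept[-1] = p
    times = ecg.t0 + np.asarray(kept) / fs
    return NNSeries.from_times(times)
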