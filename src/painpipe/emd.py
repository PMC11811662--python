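"""Empirical mode decomposition by cubic-spline sifting.

Decomposes a signal into intrinsic mode functions (IMFs) by repeatedly
subtracting the mean of the upper and lower extrema envelopes until the
component is locally symmetric (standard Cauchy-type stopping criterion),
then peeling it off and continuing on the residue.  Mirror extension at
the boundaries limits end effects.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    maxima = argrelextrema(x, np.greater_equal, order=1)[0]
    minima = argrelextrema(x, np.less_equal, order=1)[0]
    # drop plateau duplicates
    maxima = maxima[np.insert(np.diff(maxima) > 1, 0, True)] if maxima.size else maxima
    minima = minima[np.insert(np.diff(minima) > 1, 0, True)] if minima.size else minima
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    # mirror the first/last extrema beyond the boundaries to anchor the spline
    t = idx.astype(float)
    v = x[idx]
    if idx.size >= 2:
        t = np.concatenate(([-t[1]], t, [2 * (n - 1) - t[-2]]))
        v = np.concatenate(([v[1]], v, [v[-2]]))
    cs = CubicSpline(t, v)
    return cs(np.arange(n))


def sift(x: np.ndarray, max_iter: int = 12, sd_thresh: float = 0.2) -> np.ndarray | None:
    """Extract one IMF from x, or None if x is monotone / has too few extrema."""
    h = x.astype(float).copy()
    n = h.size
    for _ in range(max_iter):
        maxima, minima = _extrema(h)
        if maxima.size < 2 or minima.size < 2:
            return None
        mean_env = 0.5 * (_envelope(h, maxima, n) + _envelope(h, minima, n))
        h_new = h - mean_env
        denom = np.sum(h ** 2)
        sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
        h = h_new
        if sd < sd_thresh:
            break
    return h


def emd(x: np.ndarray, max_imfs: int = 10) -> list[np.ndarray]:
    """Decompose x into IMFs; the final residue is not included."""
    x = np.asarray(x, float)
    imfs: list[np.ndarray] = []
    residue = x.copy()
    for _ in range(max_imfs):
        imf = sift(residue)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
        if np.max(np.abs(residue)) < 1e-12 * max(1.0, np.max(np.abs(x))):
            break
    return imfs


def dominant_frequency(x: np.ndarray, fs: float) -> float:
    """Frequency (Hz) of the largest FFT magnitude, excluding DC."""
    x = np.asarray(x, float)
    spec = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    if spec.size <= 1:
        return 0.0
    k = 1 + int(np.argmax(spec[1:]))
    return float(freqs[k])
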