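"""Windowed handcrafted feature extraction for all four modalities.

Per window the extractors emit fixed, ordered feature vectors:

* ECG — 19 time-domain heart-rate-variability features from NN intervals,
* EMG — 14 amplitude/variability features per channel × 5 channels = 70,
* EDA — 12 statistics over the clean signal plus the phasic peak count,
* RR  — 10 respiratory features from the PPG-derived respiration signal.

Windows are 5.5 s or 10 s, non-overlapping by default.  A window whose
features cannot be computed (e.g. fewer than two R-peaks) carries NaN and
is dropped from the assembled feature matrix with a logged count.

Statistical conventions: standard deviations are population SDs (ddof=0);
NN-difference minima/maxima are signed (an absolute-value variant is
available via configuration); local extrema use strict neighbor
comparison, plateaus contribute their first sample, and windows with no
interior extremum fall back to the window max/min (hence the constant
value on constant windows).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import find_peaks, hilbert

from .config import FeaturesConfig
from .cvxeda import PhasicDecomposition, eda_decompose
from .emd import dominant_frequency, emd
from .preprocess import butterworth_filter, FilterSpec
from .rpeaks import NNSeries, NoPeaksError, detect_r_peaks
from .types import FeatureWindow, Recording, Signal

log = logging.getLogger("painpipe")

RESP_BAND = (0.1, 0.5)  # Hz, plausible adult respiratory range

ECG_FEATURES = [
    "nn_slope", "nn_count", "nn_mean", "nn_min", "nn_max", "nn_sd",
    "diff_mean", "diff_min", "diff_max", "sdsd", "rmssd",
    "nn20_count", "nn50_count", "pnn20", "pnn50",
    "hr_mean", "hr_min", "hr_max", "hr_sd",
]
EMG_CHANNEL_FEATURES = [
    "peak", "p2p_mean", "rms", "masd2", "masd1", "masd2_norm", "masd1_norm",
    "local_min_mean", "local_max_mean", "mean_abs",
    "variance", "sd", "range", "iqr",
]
EDA_FEATURES = [
    "n_phasic_peaks", "mean", "max", "min", "max_minus_min", "sd", "iqr",
    "rms", "local_min_mean", "local_max_mean", "mad1", "mad2",
]
RR_FEATURES = [
    "n_inhale_peaks", "mean", "max", "min", "max_minus_min", "sd",
    "peak_interval_mean", "peak_interval_sd", "peak_interval_rmssd",
    "inhale_duration_sd",
]


def emg_feature_names(n_channels: int = 5) -> list[str]:
    return [f"ch{c + 1}_{f}" for c in range(n_channels)
            for f in EMG_CHANNEL_FEATURES]


# ---------------------------------------------------------------- windows

def sliding_windows(sig: Signal, window_len: float,
                    step_s: float | None = None) -> list[tuple[float, np.ndarray]]:
    """Cut a signal into fixed-length windows.

    Returns ``(t_start, samples)`` pairs with exactly
    ``round(window_len * fs)`` samples each; the default step equals the
    window length (non-overlapping).  A signal shorter than one window
    yields an empty list with a warning.
    """
    step_s = window_len if step_s is None else step_s
    n = int(round(window_len * sig.fs))
    step = max(1, int(round(step_s * sig.fs)))
    if n > sig.samples.size:
        log.warning("signal %r shorter than one %.1f s window", sig.name, window_len)
        return []
    out = []
    for start in range(0, sig.samples.size - n + 1, step):
        out.append((sig.t0 + start / sig.fs, sig.samples[start:start + n]))
    return out


# ---------------------------------------------------------------- helpers

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict local minima/maxima values; plateaus count once (first sample)."""
    # compress runs of equal consecutive values, remember first index of run
    keep = np.concatenate(([True], np.diff(x) != 0))
    xc = x[keep]
    maxima, minima = [], []
    for i in range(1, xc.size - 1):
        if xc[i] > xc[i - 1] and xc[i] > xc[i + 1]:
            maxima.append(xc[i])
        elif xc[i] < xc[i - 1] and xc[i] < xc[i + 1]:
            minima.append(xc[i])
    return np.asarray(minima, float), np.asarray(maxima, float)


def _extrema_means(x: np.ndarray) -> tuple[float, float]:
    minima, maxima = _local_extrema(x)
    lo = float(np.mean(minima)) if minima.size else float(np.min(x))
    hi = float(np.mean(maxima)) if maxima.size else float(np.max(x))
    return lo, hi


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


# -------------------------------------------------------------------- ECG

def hrv_time_features(nn: NNSeries, abs_diff_extrema: bool = False) -> np.ndarray:
    """19 time-domain HRV features from an NN-interval series (ms).

    Needs at least two NN intervals (one successive difference); otherwise
    returns a NaN vector as the missing-feature sentinel.
    """
    x = nn.nn_ms
    out = np.full(len(ECG_FEATURES), np.nan)
    if x.size < 2:
        return out
    d = np.diff(x)
    dx = np.abs(d) if abs_diff_extrema else d
    idx = np.arange(x.size)
    slope = np.polyfit(idx, x, 1)[0]
    hr = 60000.0 / x
    nn20 = int(np.sum(np.abs(d) > 20.0))
    nn50 = int(np.sum(np.abs(d) > 50.0))
    vals = [
        slope, float(x.size), x.mean(), x.min(), x.max(), x.std(),
        d.mean(), dx.min(), dx.max(), d.std(), np.sqrt(np.mean(d ** 2)),
        nn20, nn50, 100.0 * nn20 / d.size, 100.0 * nn50 / d.size,
        hr.mean(), hr.min(), hr.max(), hr.std(),
    ]
    out[:] = vals
    return out


# -------------------------------------------------------------------- EMG

def emg_features(x: np.ndarray, fs: float,
                 p2p_subframe_s: float = 0.5) -> np.ndarray:
    """14 amplitude and variability features for one EMG channel window."""
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("empty EMG window")
    sub = max(1, int(round(p2p_subframe_s * fs)))
    p2p = [np.ptp(x[i:i + sub]) for i in range(0, x.size, sub)]
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    lo, hi = _extrema_means(x)

    def masd(v, k):  # mean absolute k-th difference
        return float(np.mean(np.abs(np.diff(v, n=k)))) if v.size > k else 0.0

    return np.array([
        np.max(np.abs(x)), float(np.mean(p2p)), np.sqrt(np.mean(x ** 2)),
        masd(x, 2), masd(x, 1), masd(z, 2), masd(z, 1),
        lo, hi, np.mean(np.abs(x)),
        x.var(), sd, np.ptp(x), _iqr(x),
    ])


# -------------------------------------------------------------------- EDA

def eda_features(clean: np.ndarray, phasic: np.ndarray, fs: float,
                 peak_prominence: float = 0.01) -> np.ndarray:
    """12 EDA features: phasic peak count + statistics of the clean window."""
    clean = np.asarray(clean, float)
    peaks, _ = find_peaks(phasic, prominence=peak_prominence)
    lo, hi = _extrema_means(clean)

    def mad(v, k):
        return float(np.mean(np.abs(np.diff(v, n=k)))) if v.size > k else 0.0

    return np.array([
        float(peaks.size), clean.mean(), clean.max(), clean.min(),
        np.ptp(clean), clean.std(), _iqr(clean),
        np.sqrt(np.mean(clean ** 2)), lo, hi, mad(clean, 1), mad(clean, 2),
    ])


# --------------------------------------------------------------------- RR

class NoRespiratoryComponent(RuntimeError):
    pass


def derive_respiration(ppg: Signal, min_rel_amplitude: float = 0.1) -> Signal:
    """Derive a respiration signal from preprocessed PPG via EMD.

    Respiratory information in PPG lives both in additive baseline
    oscillation and in amplitude modulation of the cardiac pulse.  The
    derivation therefore (1) runs empirical mode decomposition on the
    filtered PPG and keeps IMFs whose dominant frequency lies in the
    respiratory band (0.1–0.5 Hz); (2) demodulates the cardiac amplitude
    (Hilbert envelope) and runs EMD on the envelope, again keeping
    in-band IMFs.  Whichever route yields the stronger in-band component
    (relative to a floor of ``min_rel_amplitude`` times the PPG's SD) is
    returned.  Raises :class:`NoRespiratoryComponent` if both fail.
    """
    if ppg.duration < 30.0:
        raise ValueError("need >= 30 s of PPG to derive respiration")
    x = ppg.samples
    floor = min_rel_amplitude * x.std()

    def in_band_sum(sig_arr: np.ndarray) -> np.ndarray | None:
        comps = [imf for imf in emd(sig_arr)
                 if RESP_BAND[0] <= dominant_frequency(imf, ppg.fs) <= RESP_BAND[1]
                 and imf.std() >= floor]
        return np.sum(comps, axis=0) if comps else None

    env = np.abs(hilbert(x - x.mean()))
    candidates = [r for r in (in_band_sum(x), in_band_sum(env - env.mean()))
                  if r is not None]
    if not candidates:
        raise NoRespiratoryComponent("no IMF in the respiratory band")
    resp = max(candidates, key=lambda r: r.std())
    return ppg.copy_with(resp, name="resp")


def rr_features(x: np.ndarray, fs: float, prominence_frac: float = 0.2,
                min_spacing_s: float = 1.5) -> np.ndarray:
    """10 respiratory features from one respiration-signal window."""
    x = np.asarray(x, float)
    out = np.full(len(RR_FEATURES), np.nan)
    rng = np.ptp(x)
    if rng == 0:
        return out
    dist = max(1, int(round(min_spacing_s * fs)))
    peaks, _ = find_peaks(x, prominence=prominence_frac * rng, distance=dist)
    troughs, _ = find_peaks(-x, prominence=prominence_frac * rng, distance=dist)

    out[0] = float(peaks.size)
    out[1:6] = [x.mean(), x.max(), x.min(), rng, x.std()]
    if peaks.size >= 2:
        iv = np.diff(peaks) / fs
        out[6] = iv.mean()
        out[7] = iv.std()
        div = np.diff(iv)
        out[8] = np.sqrt(np.mean(div ** 2)) if div.size else 0.0
    # inhale duration: preceding trough -> peak
    durations = []
    for p in peaks:
        prior = troughs[troughs < p]
        if prior.size:
            durations.append((p - prior[-1]) / fs)
    if len(durations) >= 1:
        out[9] = float(np.std(durations))
    return out


# -------------------------------------------------------- full extraction

def _window_grid(duration: float, window_len: float, step_s: float) -> list[float]:
    starts = []
    t = 0.0
    while t + window_len <= duration + 1e-9:
        starts.append(round(t, 9))
        t += step_s
    return starts


def extract_handcrafted(rec: Recording, window_len: float | None = None,
                        cfg: FeaturesConfig | None = None,
                        drop_missing: bool = True) -> list[FeatureWindow]:
    """Extract per-window handcrafted features for every modality present.

    The recording must already be preprocessed.  All modalities share one
    window grid in seconds so that windows align across modalities for
    fusion.  Windows containing NaN features are dropped (count logged)
    unless ``drop_missing`` is False.
    """
    cfg = cfg or FeaturesConfig()
    window_len = cfg.window_len if window_len is None else window_len
    step_s = cfg.step_s or window_len
    duration = rec.duration()
    starts = _window_grid(duration, window_len, step_s)

    windows: list[FeatureWindow] = []
    dropped = 0

    def emit(modality, t0, values, names):
        nonlocal dropped
        values = np.asarray(values, float)
        if drop_missing and not np.all(np.isfinite(values)):
            dropped += 1
            return
        windows.append(FeatureWindow(
            subject_id=rec.subject_id, modality=modality, t_start=t0,
            t_end=t0 + window_len, window_len=window_len,
            values=values, names=names))

    if "ECG" in rec.channels:
        ecg = rec.channels["ECG"][0]
        try:
            nn_all = detect_r_peaks(ecg)
            peak_times = nn_all.r_peak_times
        except NoPeaksError:
            peak_times = np.array([])
        for t0 in starts:
            sel = peak_times[(peak_times >= t0) & (peak_times < t0 + window_len)]
            if sel.size >= 3:
                feats = hrv_time_features(NNSeries.from_times(sel),
                                          cfg.abs_nn_diff_extrema)
            else:
                feats = np.full(len(ECG_FEATURES), np.nan)
            emit("ECG", t0, feats, ECG_FEATURES)

    if "EMG" in rec.channels:
        chans = rec.channels["EMG"]
        fs = chans[0].fs
        names = emg_feature_names(len(chans))
        for t0 in starts:
            vals = []
            for ch in chans:
                i0 = int(round((t0 - ch.t0) * fs))
                seg = ch.samples[i0:i0 + int(round(window_len * fs))]
                vals.append(emg_features(seg, fs, cfg.emg_p2p_subframe_s))
            emit("EMG", t0, np.concatenate(vals), names)

    if "EDA" in rec.channels:
        eda = rec.channels["EDA"][0]
        decomp = eda_decompose(eda)
        n = int(round(window_len * eda.fs))
        for t0 in starts:
            i0 = int(round((t0 - eda.t0) * eda.fs))
            emit("EDA", t0,
                 eda_features(eda.samples[i0:i0 + n],
                              decomp.phasic[i0:i0 + n], eda.fs,
                              cfg.scr_peak_prominence),
                 EDA_FEATURES)

    if "PPG" in rec.channels:
        ppg = rec.channels["PPG"][0]
        try:
            resp = derive_respiration(ppg)
        except (NoRespiratoryComponent, ValueError) as exc:
            log.warning("subject %s: %s; RR features skipped", rec.subject_id, exc)
            resp = None
        if resp is not None:
            n = int(round(window_len * resp.fs))
            for t0 in starts:
                i0 = int(round((t0 - resp.t0) * resp.fs))
                emit("RR", t0,
                     rr_features(resp.samples[i0:i0 + n], resp.fs,
                                 cfg.inhale_prominence_frac,
                                 cfg.inhale_min_spacing_s),
                     RR_FEATURES)

    if dropped:
        log.info("subject %s: dropped %d windows with missing features",
                 rec.subject_id, dropped)
    return windows
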