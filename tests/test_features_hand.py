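"""Handcrafted feature extractors against hand-computed and brute-force
oracles."""

import numpy as np
import pytest

from painpipe.cvxeda import eda_decompose
from painpipe.emd import dominant_frequency
from painpipe.features import (ECG_FEATURES, EDA_FEATURES,
                               EMG_CHANNEL_FEATURES, RR_FEATURES,
                               NoRespiratoryComponent, derive_respiration,
                               eda_features, emg_feature_names, emg_features,
                               extract_handcrafted, hrv_time_features,
                               rr_features, sliding_windows)
from painpipe.rpeaks import NNSeries, NoPeaksError, detect_r_peaks
from painpipe.types import Signal


def template_ecg(beat_times, fs=500.0, duration=30.0):
    """Clean synthetic ECG: Gaussian R spikes plus small T waves."""
    n = int(duration * fs)
    x = np.zeros(n)
    t = np.arange(n) / fs
    for bt in beat_times:
        x += 1.0 * np.exp(-0.5 * ((t - bt) / 0.012) ** 2)
        x += 0.15 * np.exp(-0.5 * ((t - bt - 0.25) / 0.06) ** 2)
    return Signal(x, fs, 0.0, "ecg")


class TestSlidingWindows:
    @pytest.mark.parametrize("dur,wl,expected", [(60, 10.0, 6), (60, 5.5, 10)])
    def test_counts(self, dur, wl, expected):
        sig = Signal(np.zeros(int(dur * 10)), 10.0)
        wins = sliding_windows(sig, wl)
        assert len(wins) == expected
        assert all(w.size == round(wl * 10) for _, w in wins)

    def test_short_signal_empty(self):
        assert sliding_windows(Signal(np.zeros(50), 10.0), 10.0) == []

    def test_overlap_step(self):
        sig = Signal(np.zeros(600), 10.0)
        assert len(sliding_windows(sig, 10.0, step_s=5.0)) == 11


class TestRPeaks:
    def test_metronome_beats_recovered(self):
        beats = np.arange(0.5, 30.0, 1.0)
        nn = detect_r_peaks(template_ecg(beats))
        assert abs(len(nn.r_peak_times) - 30) <= 1
        assert np.all(np.abs(nn.nn_ms - 1000.0) < 5.0)

    def test_flat_signal_raises(self):
        with pytest.raises(NoPeaksError):
            detect_r_peaks(Signal(np.zeros(15000), 500.0))

    def test_deleted_beat_doubles_interval(self):
        beats = np.delete(np.arange(0.5, 30.0, 1.0), 10)
        nn = detect_r_peaks(template_ecg(beats))
        assert np.sum(np.abs(nn.nn_ms - 2000.0) < 20.0) == 1


def hrv_oracle(nn_ms):
    """Independent brute-force transcription of the 19 HRV definitions."""
    nn = [float(v) for v in nn_ms]
    n = len(nn)
    d = [nn[i + 1] - nn[i] for i in range(n - 1)]
    mean = sum(nn) / n
    xbar = (n - 1) / 2.0
    slope = (sum((i - xbar) * (v - mean) for i, v in enumerate(nn))
             / sum((i - xbar) ** 2 for i in range(n)))
    sd = (sum((v - mean) ** 2 for v in nn) / n) ** 0.5
    dmean = sum(d) / len(d)
    dsd = (sum((v - dmean) ** 2 for v in d) / len(d)) ** 0.5
    rmssd = (sum(v * v for v in d) / len(d)) ** 0.5
    nn20 = sum(1 for v in d if abs(v) > 20.0)
    nn50 = sum(1 for v in d if abs(v) > 50.0)
    hr = [60000.0 / v for v in nn]
    hmean = sum(hr) / n
    hsd = (sum((v - hmean) ** 2 for v in hr) / n) ** 0.5
    return [slope, n, mean, min(nn), max(nn), sd,
            dmean, min(d), max(d), dsd, rmssd,
            nn20, nn50, 100.0 * nn20 / len(d), 100.0 * nn50 / len(d),
            hmean, min(hr), max(hr), hsd]


class TestHRV:
    def test_constant_series(self):
        feats = dict(zip(ECG_FEATURES,
                         hrv_time_features(NNSeries(np.arange(11) * 0.8,
                                                    np.full(10, 800.0)))))
        assert feats["nn_mean"] == 800
        assert feats["nn_sd"] == 0 and feats["rmssd"] == 0
        assert feats["sdsd"] == 0 and feats["pnn20"] == 0
        assert feats["hr_mean"] == 75
        assert abs(feats["nn_slope"]) < 1e-9

    def test_hand_computed_example(self):
        nn = NNSeries(np.array([0, .8, 1.61, 2.4, 3.205]),
                      np.array([800.0, 810.0, 790.0, 805.0]))
        feats = dict(zip(ECG_FEATURES, hrv_time_features(nn)))
        assert feats["nn_count"] == 4
        assert abs(feats["rmssd"] - np.sqrt((100 + 400 + 225) / 3)) < 1e-9
        assert feats["nn20_count"] == 0
        assert feats["diff_min"] == -20 and feats["diff_max"] == 15

    def test_two_interval_series(self):
        nn = NNSeries(np.array([0, .7, 1.46]), np.array([700.0, 760.0]))
        feats = dict(zip(ECG_FEATURES, hrv_time_features(nn)))
        assert feats["nn50_count"] == 1 and feats["pnn50"] == 100

    def test_single_interval_gives_sentinel(self):
        nn = NNSeries(np.array([0, .7]), np.array([700.0]))
        assert np.all(np.isnan(hrv_time_features(nn)))

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            nn_ms = rng.uniform(400.0, 1500.0, size=n)
            times = np.concatenate([[0.0], np.cumsum(nn_ms) / 1000.0])
            got = hrv_time_features(NNSeries(times, nn_ms))
            want = np.asarray(hrv_oracle(nn_ms), float)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-9)


class TestEMG:
    def test_constant_window(self):
        f = dict(zip(EMG_CHANNEL_FEATURES, emg_features(np.full(500, 2.0), 500.0)))
        assert f["peak"] == 2 and f["rms"] == 2 and f["mean_abs"] == 2
        assert f["masd1"] == 0 and f["variance"] == 0
        assert f["range"] == 0 and f["iqr"] == 0
        assert f["local_min_mean"] == 2 and f["local_max_mean"] == 2

    def test_square_wave_window(self):
        x = np.resize([0.0, 1.0, 0.0, -1.0], 400)
        f = dict(zip(EMG_CHANNEL_FEATURES, emg_features(x, 500.0)))
        assert abs(f["rms"] - np.sqrt(0.5)) < 1e-12
        assert f["range"] == 2 and f["mean_abs"] == 0.5

    def test_five_channels_make_70(self):
        assert len(emg_feature_names(5)) == 70

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        c = 3.7
        f1 = dict(zip(EMG_CHANNEL_FEATURES, emg_features(x, 500.0)))
        f2 = dict(zip(EMG_CHANNEL_FEATURES, emg_features(c * x, 500.0)))
        for name in ("rms", "peak", "sd", "range"):
            assert abs(f2[name] - c * f1[name]) < 1e-8
        for name in ("masd1_norm", "masd2_norm"):
            assert abs(f2[name] - f1[name]) < 1e-8


def bateman(t, tau0=0.7, tau1=2.0):
    h = np.exp(-t / tau1) - np.exp(-t / tau0)
    return h / h.max()


class TestEDADecomposition:
    fs = 4.0

    def test_slow_ramp_is_tonic(self):
        y = np.linspace(2.0, 3.0, int(60 * self.fs))
        dec = eda_decompose(Signal(y, self.fs))
        assert np.sum(dec.phasic ** 2) < 0.05 * np.sum((y - y.mean()) ** 2)

    def test_injected_scrs_counted(self):
        from scipy.signal import find_peaks
        n = int(120 * self.fs)
        t = np.arange(n) / self.fs
        y = 2.0 + 0.002 * t
        kernel = bateman(np.arange(0, 20, 1 / self.fs))
        for st in (20.0, 55.0, 90.0):
            i0 = int(st * self.fs)
            y[i0:i0 + kernel.size] += 0.4 * kernel[:n - i0]
        dec = eda_decompose(Signal(y, self.fs))
        peaks, _ = find_peaks(dec.phasic, prominence=0.01)
        assert peaks.size == 3

    def test_zero_signal(self):
        dec = eda_decompose(Signal(np.zeros(100), self.fs))
        assert np.all(dec.tonic == 0) and np.all(dec.phasic == 0)

    def test_additivity_and_nonnegativity(self, preprocessed_subject):
        rec, _ = preprocessed_subject
        eda = rec.channels["EDA"][0]
        dec = eda_decompose(eda)
        assert np.max(np.abs(dec.total - eda.samples)) < 1e-6
        assert dec.phasic.min() > -1e-9


class TestEDAFeatures:
    def test_constant_window(self):
        f = dict(zip(EDA_FEATURES,
                     eda_features(np.ones(40), np.zeros(40), 4.0)))
        assert f["n_phasic_peaks"] == 0
        assert f["mean"] == f["max"] == f["min"] == f["rms"] == 1
        assert f["max_minus_min"] == 0 and f["sd"] == 0

    def test_vector_length_12(self):
        rng = np.random.default_rng(0)
        v = eda_features(rng.normal(size=40), rng.normal(size=40) ** 2, 4.0)
        assert v.size == 12 == len(EDA_FEATURES)

    def test_two_scrs_in_window(self):
        fs = 4.0
        n = int(40 * fs)
        phasic = np.zeros(n)
        kernel = bateman(np.arange(0, 15, 1 / fs))
        for st in (5.0, 25.0):
            i0 = int(st * fs)
            phasic[i0:i0 + kernel.size] += 0.3 * kernel[:n - i0]
        f = dict(zip(EDA_FEATURES, eda_features(np.ones(n), phasic, fs)))
        assert f["n_phasic_peaks"] == 2


class TestRespiration:
    fs = 64.0

    def modulated_ppg(self, f_mod, duration=60.0, m=0.35):
        t = np.arange(int(duration * self.fs)) / self.fs
        x = (1 + m * np.sin(2 * np.pi * f_mod * t)) * np.sin(2 * np.pi * 1.2 * t)
        return Signal(x, self.fs, 0.0, "ppg")

    @pytest.mark.parametrize("f_mod", [0.25, 0.45])
    def test_modulation_frequency_recovered(self, f_mod):
        resp = derive_respiration(self.modulated_ppg(f_mod))
        assert abs(dominant_frequency(resp.samples, resp.fs) - f_mod) < 0.02

    def test_unmodulated_carrier_raises(self):
        t = np.arange(int(60 * self.fs)) / self.fs
        sig = Signal(np.sin(2 * np.pi * 1.2 * t), self.fs)
        with pytest.raises(NoRespiratoryComponent):
            derive_respiration(sig)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            derive_respiration(self.modulated_ppg(0.25, duration=20.0))


class TestRRFeatures:
    def test_quarter_hz_sine_full_minute(self):
        fs = 8.0
        t = np.arange(int(60 * fs)) / fs
        f = dict(zip(RR_FEATURES, rr_features(np.sin(2 * np.pi * 0.25 * t), fs)))
        assert f["n_inhale_peaks"] == 15
        assert abs(f["peak_interval_mean"] - 4.0) < 1e-6
        assert f["peak_interval_sd"] < 1e-6

    def test_ten_second_window(self):
        fs = 8.0
        t = np.arange(int(10 * fs)) / fs
        f = dict(zip(RR_FEATURES, rr_features(np.sin(2 * np.pi * 0.25 * t), fs)))
        assert f["n_inhale_peaks"] in (2, 3)
        assert abs(f["peak_interval_mean"] - 4.0) < 0.26  # one-sample quantization

    def test_vector_length_10(self):
        fs = 8.0
        t = np.arange(int(30 * fs)) / fs
        v = rr_features(np.sin(2 * np.pi * 0.25 * t), fs)
        assert v.size == 10 == len(RR_FEATURES)

    def test_single_peak_interval_sentinels(self):
        fs = 8.0
        t = np.arange(int(5 * fs)) / fs
        f = dict(zip(RR_FEATURES, rr_features(np.sin(2 * np.pi * 0.25 * t), fs)))
        assert np.isnan(f["peak_interval_mean"])


class TestFullExtraction:
    def test_window_counts_and_cardinalities(self, preprocessed_subject):
        rec, _ = preprocessed_subject
        windows = extract_handcrafted(rec, 10.0)
        by_mod = {}
        for w in windows:
            by_mod.setdefault(w.modality, []).append(w)
        expected_len = {"ECG": 19, "EMG": 70, "EDA": 12, "RR": 10}
        for mod, exp in expected_len.items():
            assert mod in by_mod
            assert all(len(w.values) == exp for w in by_mod[mod])
            assert all(len(w.names) == exp for w in by_mod[mod])
            # 240 s / 10 s = 24 windows, minus possible missing-feature drops
            assert 20 <= len(by_mod[mod]) <= 24

    def test_column_stability_across_runs(self, preprocessed_subject):
        rec, _ = preprocessed_subject
        w1 = extract_handcrafted(rec, 10.0)
        w2 = extract_handcrafted(rec, 10.0)
        assert len(w1) == len(w2)
        for a, b in zip(w1, w2):
            assert a.names == b.names
            np.testing.assert_array_equal(a.values, b.values)
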