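"""Synthetic multimodal cohort generator.

Emulates a postoperative monitoring session: each subject's recording
starts with a rest (baseline) period and continues with light-activity
segments during which pain is felt and sparsely self-reported on the NRS.
Pain of intensity ``nrs`` shifts the physiology monotonically:

* heart rate rises by ``hr_bpm_per_nrs`` (default +1.5 bpm/point) while
  HRV (the SD of inter-beat intervals) shrinks by ``sdnn_shrink_per_nrs``
  (default 5 %/point, multiplicative),
* facial EMG bursts grow in amplitude by ``emg_gain_per_nrs`` (default
  +15 %/point),
* skin-conductance responses occur more often
  (``scr_rate_per_nrs``, default +0.4 SCR/min/point), and
* respiration quickens by ``rr_bpm_per_nrs`` (default +0.5 breaths/min/
  point), expressed in the PPG as amplitude modulation of the cardiac
  pulse.

Per-subject random baselines (resting heart rate 55–85 bpm, tonic EDA
level, resting respiration 12–16 breaths/min) create the inter-subject
variability that makes leave-one-subject-out evaluation meaningful.  A
ground-truth table records true beat times, SCR event times, respiratory
frequency per segment, and the true class over time.

ECG morphology is a simple P-QRS-T Gaussian template — adequate for
R-peak timing and HRV, not for waveform-shape studies.  Motion artifacts
are random amplitude bursts added to all contact signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import PainAnnotation, Recording, Signal


@dataclass
class CohortSpec:
    n_subjects: int = 20
    duration_s: float = 600.0
    n_activity_segments: int = 6
    baseline_frac: float = 0.2          # leading rest period, >= 60 s if possible
    # effect sizes per NRS point
    hr_bpm_per_nrs: float = 1.5
    sdnn_shrink_per_nrs: float = 0.05
    emg_gain_per_nrs: float = 0.15
    scr_rate_per_nrs: float = 0.4       # extra SCRs per minute per point
    rr_bpm_per_nrs: float = 0.5
    # baselines
    sdnn_ms: float = 50.0
    scr_base_per_min: float = 2.0
    emg_burst_base: float = 0.5         # mV burst envelope amplitude
    # sampling rates (Hz)
    fs_ecg: float = 500.0
    fs_emg: float = 500.0
    fs_eda: float = 4.0
    fs_ppg: float = 64.0
    # noise / artifacts
    noise_scale: float = 1.0            # 0 -> clean signals
    motion_prob_per_min: float = 1.0
    motion_amp: float = 0.5
    # labels
    annotations_per_segment: int = 2
    pain_profile: list[int] | None = None   # per-segment NRS, else random
    seed: int = 0

    def hr_bpm(self, nrs: float, hr0: float = 70.0) -> float:
        return hr0 + self.hr_bpm_per_nrs * nrs

    def sdnn(self, nrs: float) -> float:
        return self.sdnn_ms * (1.0 - self.sdnn_shrink_per_nrs) ** nrs

    def scr_rate_per_min(self, nrs: float) -> float:
        return self.scr_base_per_min + self.scr_rate_per_nrs * nrs

    def resp_bpm(self, nrs: float, rr0: float = 14.0) -> float:
        return rr0 + self.rr_bpm_per_nrs * nrs

    def emg_burst_amp(self, nrs: float) -> float:
        return self.emg_burst_base * (1.0 + self.emg_gain_per_nrs * nrs)


@dataclass
class GroundTruth:
    subject_id: str
    beat_times: np.ndarray
    scr_times: np.ndarray
    segments: list[tuple[float, float, int]]    # (t0, t1, nrs)
    baseline_span: tuple[float, float]
    resp_freq_hz: dict[int, float]              # per segment index
    hr0: float
    rr0: float

    def nrs_at(self, t: float) -> int:
        for t0, t1, nrs in self.segments:
            if t0 <= t < t1:
                return nrs
        return 0


def _segment_layout(spec: CohortSpec) -> tuple[tuple[float, float], list[tuple[float, float]]]:
    base_len = max(min(60.0, 0.5 * spec.duration_s), spec.baseline_frac * spec.duration_s)
    remaining = spec.duration_s - base_len
    n = spec.n_activity_segments
    gap = 0.1 * remaining / max(n, 1)
    seg_len = (remaining - gap * n) / n
    if seg_len < 20.0:
        raise ValueError(
            f"duration {spec.duration_s}s too short for {n} activity segments")
    spans = []
    t = base_len
    for _ in range(n):
        t += gap
        spans.append((t, t + seg_len))
        t += seg_len
    return (2.0, base_len - 2.0), spans


def _default_pain_profile(n: int, rng: np.random.Generator) -> list[int]:
    # one segment per pain class guaranteed; extras mid-heavy, mimicking the
    # imbalance of real self-reports (few extreme scores, many moderate)
    prof = [int(rng.integers(1, 4)), int(rng.integers(4, 7)),
            int(rng.integers(7, 11))]
    weights = np.array([1, 2, 4, 6, 8, 6, 4, 2, 1, 0.5], float)
    weights /= weights.sum()
    for _ in range(n - 3):
        prof.append(int(rng.choice(np.arange(1, 11), p=weights)))
    rng.shuffle(prof)
    return prof[:n]


def _add_gauss(y: np.ndarray, fs: float, t_center: float, amp: float,
               sigma_s: float) -> None:
    half = int(4 * sigma_s * fs) + 1
    c = int(round(t_center * fs))
    a, b = max(0, c - half), min(y.size, c + half + 1)
    if a >= b:
        return
    t = (np.arange(a, b) / fs) - t_center
    y[a:b] += amp * np.exp(-0.5 * (t / sigma_s) ** 2)


def _gen_beat_times(spec: CohortSpec, gt_nrs, hr0: float, duration: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Inter-beat intervals follow an AR(1) around the pain-shifted mean."""
    times = [0.3]
    dev = 0.0
    phi = 0.8
    while times[-1] < duration:
        nrs = gt_nrs(times[-1])
        mean_ms = 60000.0 / spec.hr_bpm(nrs, hr0)
        sd_ms = spec.sdnn(nrs) * spec.noise_scale
        innov_sd = sd_ms * np.sqrt(max(1e-12, 1 - phi ** 2))
        dev = phi * dev + rng.normal(0.0, innov_sd)
        rr_ms = np.clip(mean_ms + dev, 300.0, 2000.0)
        times.append(times[-1] + rr_ms / 1000.0)
    return np.array(times[:-1])


def _motion_bursts(n: int, fs: float, spec: CohortSpec,
                   rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    if spec.noise_scale == 0 or spec.motion_prob_per_min <= 0:
        return out
    n_bursts = rng.poisson(spec.motion_prob_per_min * n / fs / 60.0)
    for _ in range(n_bursts):
        t0 = rng.uniform(0, n / fs)
        dur = rng.uniform(0.3, 1.5)
        i0, i1 = int(t0 * fs), min(n, int((t0 + dur) * fs))
        if i1 > i0:
            env = np.hanning(i1 - i0)
            out[i0:i1] += spec.motion_amp * env * rng.normal(size=i1 - i0)
    return out * spec.noise_scale


def generate_subject(spec: CohortSpec, subject_seed: int,
                     subject_id: str | None = None
                     ) -> tuple[Recording, GroundTruth]:
    """Synthesize one subject's multimodal recording with ground truth."""
    rng = np.random.default_rng(subject_seed)
    sid = subject_id or f"S{subject_seed:04d}"
    base_span, seg_spans = _segment_layout(spec)
    profile = spec.pain_profile or _default_pain_profile(
        spec.n_activity_segments, rng)
    if len(profile) != spec.n_activity_segments:
        raise ValueError("pain_profile length != n_activity_segments")
    segments = [(a, b, int(n)) for (a, b), n in zip(seg_spans, profile)]

    hr0 = rng.uniform(55.0, 85.0)
    rr0 = rng.uniform(12.0, 16.0)
    tonic0 = rng.uniform(2.0, 8.0)
    dur = spec.duration_s

    def nrs_at(t: float) -> int:
        for t0, t1, nrs in segments:
            if t0 <= t < t1:
                return nrs
        return 0

    # ---- ECG -------------------------------------------------------
    n_ecg = int(dur * spec.fs_ecg)
    ecg = np.zeros(n_ecg)
    beat_times = _gen_beat_times(spec, nrs_at, hr0, dur, rng)
    for bt in beat_times:
        _add_gauss(ecg, spec.fs_ecg, bt - 0.18, 0.08, 0.03)   # P
        _add_gauss(ecg, spec.fs_ecg, bt, 1.0, 0.012)          # R
        _add_gauss(ecg, spec.fs_ecg, bt + 0.25, 0.15, 0.06)   # T
    t_ecg = np.arange(n_ecg) / spec.fs_ecg
    ecg += spec.noise_scale * (
        0.05 * np.sin(2 * np.pi * 0.05 * t_ecg)               # baseline wander
        + rng.normal(0, 0.02, n_ecg))
    ecg += 0.3 * _motion_bursts(n_ecg, spec.fs_ecg, spec, rng)

    # ---- EMG (5 facial channels) -----------------------------------
    n_emg = int(dur * spec.fs_emg)
    emg_channels = []
    for ch in range(5):
        x = spec.noise_scale * rng.normal(0, 0.05, n_emg)
        for t0, t1, nrs in segments:
            amp = spec.emg_burst_amp(nrs)
            n_bursts = max(1, rng.poisson(4 * (t1 - t0) / 60.0))
            for _ in range(n_bursts):
                bt = rng.uniform(t0, t1 - 1.0)
                blen = rng.uniform(0.4, 1.2)
                i0, i1 = int(bt * spec.fs_emg), int((bt + blen) * spec.fs_emg)
                i1 = min(i1, n_emg)
                env = np.hanning(i1 - i0)
                x[i0:i1] += amp * env * rng.normal(size=i1 - i0)
        x += 0.2 * _motion_bursts(n_emg, spec.fs_emg, spec, rng)
        emg_channels.append(Signal(x, spec.fs_emg, 0.0, f"emg{ch + 1}"))

    # ---- EDA -------------------------------------------------------
    n_eda = int(dur * spec.fs_eda)
    t_eda = np.arange(n_eda) / spec.fs_eda
    eda = tonic0 + 0.3 * np.sin(2 * np.pi * 0.003 * t_eda) + 0.0005 * t_eda
    scr_times = []
    t = 0.0
    while t < dur:
        rate = spec.scr_rate_per_min(nrs_at(t)) / 60.0
        t += rng.exponential(1.0 / rate)
        if t < dur:
            scr_times.append(t)
    kernel_t = np.arange(0, 20.0, 1.0 / spec.fs_eda)
    bateman = np.exp(-kernel_t / 2.0) - np.exp(-kernel_t / 0.7)
    bateman /= bateman.max()
    for st in scr_times:
        amp = rng.uniform(0.1, 0.5)
        i0 = int(st * spec.fs_eda)
        seg = bateman[:n_eda - i0]
        eda[i0:i0 + seg.size] += amp * seg
    eda += spec.noise_scale * rng.normal(0, 0.01, n_eda)
    eda += 0.05 * _motion_bursts(n_eda, spec.fs_eda, spec, rng)

    # ---- PPG -------------------------------------------------------
    n_ppg = int(dur * spec.fs_ppg)
    t_ppg = np.arange(n_ppg) / spec.fs_ppg
    hr_t = np.array([spec.hr_bpm(nrs_at(t), hr0) for t in t_ppg]) / 60.0
    f_resp_t = np.array([spec.resp_bpm(nrs_at(t), rr0) for t in t_ppg]) / 60.0
    cardiac_phase = 2 * np.pi * np.cumsum(hr_t) / spec.fs_ppg
    resp_phase = 2 * np.pi * np.cumsum(f_resp_t) / spec.fs_ppg
    ppg = (1.0 + 0.35 * np.sin(resp_phase)) * np.sin(cardiac_phase)
    ppg += spec.noise_scale * rng.normal(0, 0.03, n_ppg)
    ppg += 0.3 * _motion_bursts(n_ppg, spec.fs_ppg, spec, rng)

    # ---- annotations ----------------------------------------------
    annotations = []
    for t0, t1, nrs in segments:
        k = spec.annotations_per_segment
        for ts in np.sort(rng.uniform(t0 + 2, t1 - 2, size=k)):
            annotations.append(PainAnnotation(float(ts), int(nrs)))
    # a couple of explicit no-pain reports during rest
    for ts in np.sort(rng.uniform(base_span[0] + 2, base_span[1] - 2, size=2)):
        annotations.append(PainAnnotation(float(ts), 0))

    rec = Recording(
        subject_id=sid,
        channels={
            "ECG": [Signal(ecg, spec.fs_ecg, 0.0, "ecg")],
            "EMG": emg_channels,
            "EDA": [Signal(eda, spec.fs_eda, 0.0, "eda")],
            "PPG": [Signal(ppg, spec.fs_ppg, 0.0, "ppg")],
        },
        annotations=annotations,
        baseline_spans=[base_span],
    )
    truth = GroundTruth(
        subject_id=sid, beat_times=beat_times,
        scr_times=np.array(scr_times), segments=segments,
        baseline_span=base_span,
        resp_freq_hz={i: spec.resp_bpm(nrs, rr0) / 60.0
                      for i, (_, _, nrs) in enumerate(segments)},
        hr0=hr0, rr0=rr0)
    return rec, truth


def generate_cohort(spec: CohortSpec
                    ) -> list[tuple[Recording, GroundTruth]]:
    """Generate ``spec.n_subjects`` recordings with per-subject seeds."""
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(spec.seed)
    out = []
    for i, child in enumerate(ss.spawn(spec.n_subjects)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(generate_subject(spec, sub_seed, subject_id=f"S{i + 1:02d}"))
    return out
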