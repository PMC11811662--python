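"""Preprocess a recording and extract the handcrafted feature sets.

Per 10 s window the extractors emit 19 ECG (HRV), 70 EMG (14 x 5
channels), 12 EDA, and 10 respiration features.
"""

from collections import Counter

from painpipe import (CohortSpec, extract_handcrafted, generate_subject,
                      preprocess_recording)

rec, truth = generate_subject(
    CohortSpec(n_subjects=1, duration_s=240, n_activity_segments=3, seed=1),
    subject_seed=7)
pre = preprocess_recording(rec)
windows = extract_handcrafted(pre, window_len=10.0)

counts = Counter(w.modality for w in windows)
dims = {w.modality: len(w.values) for w in windows}
print("windows per modality:", dict(counts))
print("features per window: ", dims)

ecg = next(w for w in windows if w.modality == "ECG")
print(f"\nECG window {ecg.t_start:.0f}-{ecg.t_end:.0f} s:")
for name, val in list(zip(ecg.names, ecg.values))[:8]:
    print(f"  {name:12s} {val:10.3f}")
# nn_mean is the average inter-beat interval in ms (≈ 60000 / heart rate);
# rmssd and pnn50 quantify beat-to-beat variability, which drops under pain.
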