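import numpy as np
import pytest

from painpipe.config import PipelineConfig
from painpipe.synth import CohortSpec, generate_subject
from painpipe.types import PainAnnotation, Recording, Signal


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig().validate()


@pytest.fixture(scope="session")
def small_subject():
    """One 240 s synthetic subject with default noise, plus ground truth."""
    spec = CohortSpec(n_subjects=1, duration_s=240, n_activity_segments=3,
                      seed=101)
    return generate_subject(spec, 12345, subject_id="S01")


@pytest.fixture(scope="session")
def clean_subject():
    """Zero-noise subject for exact recovery checks."""
    spec = CohortSpec(n_subjects=1, duration_s=240, n_activity_segments=3,
                      seed=102, noise_scale=0.0)
    return generate_subject(spec, 54321, subject_id="S01")


@pytest.fixture(scope="session")
def preprocessed_subject(small_subject):
    from painpipe.preprocess import preprocess_recording
    rec, truth = small_subject
    return preprocess_recording(rec), truth


def sine_signal(freq, fs, duration, amp=1.0, name="sine"):
    t = np.arange(int(duration * fs)) / fs
    return Signal(amp * np.sin(2 * np.pi * freq * t), fs, 0.0, name)


@pytest.fixture
def tiny_recording():
    """Minimal schema-valid recording with two annotations."""
    fs_fast, fs_eda, fs_ppg = 500.0, 4.0, 64.0
    dur = 30.0
    rng = np.random.default_rng(0)
    mk = lambda fs, name: Signal(rng.normal(size=int(dur * fs)), fs, 0.0, name)
    return Recording(
        subject_id="T1",
        channels={
            "ECG": [mk(fs_fast, "ecg")],
            "EMG": [mk(fs_fast, f"emg{i}") for i in range(1, 6)],
            "EDA": [mk(fs_eda, "eda")],
            "PPG": [mk(fs_ppg, "ppg")],
        },
        annotations=[PainAnnotation(5.0, 0), PainAnnotation(20.0, 5)],
        baseline_spans=[(0.0, 10.0)],
    )
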