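import numpy as np
import pytest

from motionbmi import CohortSpec, SensorSequence, Window, generate_cohort


def make_window(data, subject="S001", index=1, bmi=22.0, fs=90.0):
    return Window(
        subject_id=subject,
        window_index=index,
        data=np.asarray(data, dtype=float),
        bmi_label=bmi,
        sampling_rate_hz=fs,
    )


def random_window(rng, w=30, scale=1.0, **kw):
    return make_window(rng.normal(0, scale, (6, w)), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sequence(rng):
    return SensorSequence(
        subject_id="S001",
        sampling_rate_hz=90.0,
        data=rng.normal(0, 1, (6, 450)),
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """6 subjects x 20 s: enough windows to exercise every pipeline stage."""
    spec = CohortSpec.strong_signal(n_subjects=6, duration_s=20.0, seed=42)
    return generate_cohort(spec)
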