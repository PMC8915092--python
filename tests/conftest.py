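import numpy as np
import pytest

from wristhrv import HeartRateSeries, SubjectProfile, simulate_reference


@pytest.fixture
def hr_series():
    """Complete 1-s series at ~70 bpm with mild variation."""
    rng = np.random.default_rng(42)
    values = 70 + 3 * np.sin(2 * np.pi * np.arange(200) / 12) + rng.normal(0, 0.5, 200)
    return HeartRateSeries(
        subject_id="S01",
        device_label="reference",
        timestamps=np.arange(200, dtype=float),
        values=values,
        nominal_period_s=1.0,
    )


@pytest.fixture
def smooth_sinusoid():
    """Noise-free sinusoidal HR: 900 slots, baseline 70 bpm, amplitude 5, period 12 s."""
    profile = SubjectProfile(
        baseline_hr=70.0,
        rsa_amplitude=5.0,
        rsa_period_s=12.0,
        process_noise_sd=0.0,
        beat_noise_sd=0.0,
        trend_bpm=0.0,
        seed=0,
    )
    return simulate_reference(profile)["reference"]


def make_series(values, subject_id="S01", device="wrist", period=1.0, **kw):
    values = np.asarray(values, dtype=float)
    return HeartRateSeries(
        subject_id=subject_id,
        device_label=device,
        timestamps=period * np.arange(values.size),
        values=values,
        nominal_period_s=period,
        **kw,
    )
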