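import numpy as np
import pytest

from bpwave.preprocess import FrameSet
from bpwave.signal_io import SignalRecord
from bpwave.synthetic import PhysioParams, simulate_record, sweep_bp_levels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record():
    """2,500-sample noiseless record (10 frames at 250)."""
    params = PhysioParams(noise_sd=0.0, drift_amp=0.0, seed=7)
    return simulate_record(params, duration_s=20.0, fs=125.0)


@pytest.fixture
def noisy_record():
    """Realistic record with drift and noise, 40 frames."""
    params = PhysioParams(noise_sd=0.02, drift_amp=0.3, seed=11)
    return simulate_record(params, duration_s=80.0, fs=125.0)


@pytest.fixture(scope="session")
def sweep_record():
    """Concatenated pressure sweep: 60 frames spanning the 40-180 band."""
    records = sweep_bp_levels(6, (100.0, 180.0), (40.0, 75.0), seed=3,
                              duration_s=20.0)
    return SignalRecord(
        ppg=np.concatenate([r.ppg for r in records]),
        ecg=np.concatenate([r.ecg for r in records]),
        abp=np.concatenate([r.abp for r in records]),
        fs=125.0,
        record_id="sweep-fixture",
    )


@pytest.fixture
def random_frames(rng):
    """100 random 250-sample frames as a FrameSet."""
    frames = rng.normal(size=(100, 250))
    return FrameSet(frames=frames, fs=125.0,
                    offsets=np.arange(100, dtype=np.int64) * 250)
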