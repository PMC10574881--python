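import numpy as np
import pytest

from splineqrs import CWTConfig, SimConfig, detect_record, generate_ecg


@pytest.fixture(scope="session")
def clean_minute_250():
    """One clean 60-s record at 250 Hz, 70±5 bpm, with its ground truth."""
    config = SimConfig(
        sampling_rate_hz=250.0, duration_s=60.0, mean_hr_bpm=70.0, hr_sd_bpm=5.0, seed=1
    )
    return generate_ecg(config)


@pytest.fixture(scope="session")
def detected_minute_250(clean_minute_250):
    record, truth = clean_minute_250
    beats = detect_record(record, CWTConfig(sampling_rate_hz=250.0))
    return record, truth, beats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
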