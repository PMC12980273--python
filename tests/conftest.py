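import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pharmeeg as pe

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_baseline():
    """20-s baseline spec: long enough for several epochs, fast to render."""
    return pe.BaselineSpec(duration_s=20.0)


@pytest.fixture(scope="session")
def quiet_recording(short_baseline):
    return pe.generate_baseline(short_baseline, seed=42, record_id="fixture")


@pytest.fixture(scope="session")
def feature_vector(quiet_recording):
    return pe.extract_features(quiet_recording)


def make_recording(samples, fs=500.0, **meta):
    return pe.EcogRecording(np.asarray(samples, float), fs=fs, **meta)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
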