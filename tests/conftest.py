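import numpy as np
import pytest
from hypothesis import settings

from noctox.session import OximetrySession

# deterministic, time-bounded hypothesis runs
settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_session(spo2, hr=None, participant="P01", night="night1", altitude=0.0):
    spo2 = np.asarray(spo2)
    if hr is None:
        hr = np.full(spo2.size, 60, dtype=np.int64)
    return OximetrySession(
        participant_id=participant,
        night_label=night,
        altitude_m=altitude,
        spo2=spo2,
        hr=np.asarray(hr),
    )


@pytest.fixture
def session_factory():
    return make_session


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
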