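import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from catlearn_eeg.containers import epoch_times_ms
from catlearn_eeg.montage import default_montage, scaled_montage

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def montage256():
    return default_montage()


@pytest.fixture(scope="session")
def montage64():
    return scaled_montage(64)


@pytest.fixture(scope="session")
def times_ms():
    """Canonical −200..+996 ms epoch time axis at 250 samples/s."""
    return epoch_times_ms(250.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_behavior_table(records):
    """Build a behavior table from (subject, phase, block, trial, stimulus,
    category, response) tuples; correctness is derived."""
    frame = pd.DataFrame(records, columns=["subject", "phase", "block", "trial",
                                           "stimulus_id", "category", "response"])
    frame["correct"] = frame["response"] == frame["category"]
    return frame


@pytest.fixture
def behavior_factory():
    return make_behavior_table
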