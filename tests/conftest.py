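import numpy as np
import pytest

from cowmotion.synthetic import DEFAULT_PROFILES, generate_event, generate_events


@pytest.fixture(scope="session")
def small_db():
    """Small five-behavior event list shared across tests."""
    counts = {"active_mounting": 8, "walking": 8, "resting": 8,
              "grazing": 4, "head_nodding": 8}
    return generate_events(counts, seed=2024)


@pytest.fixture(scope="session")
def mount_event():
    return generate_event(DEFAULT_PROFILES["active_mounting"], seed=11,
                          duration_s=9.0)


@pytest.fixture(scope="session")
def resting_event():
    return generate_event(DEFAULT_PROFILES["resting"], seed=12,
                          duration_s=20.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
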