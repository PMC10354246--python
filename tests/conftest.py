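import numpy as np
import pytest

import vsaslam as vs


@pytest.fixture(scope="session")
def encoder():
    """Small odd-d random-style encoder over the unit box."""
    return vs.make_encoder(61, 2, length_scale=0.15, seed=11)


@pytest.fixture(scope="session")
def readout(encoder):
    return vs.fit_normalization(encoder, 101)


@pytest.fixture(scope="session")
def full_encoder():
    """Reference-scale encoder (d=181) used by the heavier tests."""
    return vs.make_encoder(181, 2, length_scale=0.1, seed=1)


@pytest.fixture(scope="session")
def full_readout(full_encoder):
    return vs.fit_normalization(full_encoder, 101)


@pytest.fixture(scope="session")
def vocab():
    v = vs.Vocabulary(181, seed=5)
    v.populate(["BLUE", "ORANGE", "SQUARE", "TRIANGLE", "WALL"])
    return v


@pytest.fixture(scope="session")
def short_trajectory():
    return vs.generate_trajectory(0, duration=20.0, dt=1e-3, cutoff=0.2)


def pytest_configure(config):
    config.addinivalue_line(
        "markers", "slow: full-scale runs exceeding the desk budget"
    )
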