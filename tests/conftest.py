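import warnings

import numpy as np
import pytest

from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")

from triphasic import DEFAULT_CONFIG, synth  # noqa: E402


@pytest.fixture
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def small_s1_session():
    """12-unit S1 session under the standard 25-trial hand protocol."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.simulate_session(
            synth.s1_population(n_units=12), synth.ProtocolSpec(), seed=123)


@pytest.fixture(scope="session")
def medium_s1_session():
    """40-unit S1 session used for recovery-style checks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return synth.simulate_session(
            synth.s1_population(n_units=40), synth.ProtocolSpec(), seed=7)


@pytest.fixture(autouse=True)
def _quiet_overlap_warnings():
    """Protocol blocks with paired pulses legitimately overlap spans."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
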