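import numpy as np
import pytest

from spirped import (
    ADULT_TYPICAL, ADULT_VARIABILITY, DoseEvent, solve_profile,
)


@pytest.fixture(scope="session")
def adult():
    return ADULT_TYPICAL


@pytest.fixture(scope="session")
def variability():
    return ADULT_VARIABILITY


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def dense_adult_profile():
    """Densely sampled single 100 mg adult dose out to 2000 h."""
    times = np.unique(np.concatenate([
        np.arange(0.0, 24.0, 0.02),
        np.arange(24.0, 200.0, 0.25),
        np.arange(200.0, 2000.0, 2.0),
    ]))
    return solve_profile(ADULT_TYPICAL, [DoseEvent(0.0, 100.0)], times)
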