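import numpy as np
import pytest

from paleobear.enviro import (DEFAULT_PERIOD_BOUNDARIES,
                              period_scheme_from_boundaries)
from paleobear.synth import SyntheticTruth, generate_study


@pytest.fixture(scope="session")
def holocene_scheme():
    return period_scheme_from_boundaries(DEFAULT_PERIOD_BOUNDARIES)


@pytest.fixture(scope="session")
def small_study():
    """A small complete synthetic study shared across tests (8x8 grid)."""
    truth = SyntheticTruth(seed=42, nx=8, ny=8)
    return generate_study(truth)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
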