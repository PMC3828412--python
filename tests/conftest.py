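import numpy as np
import pytest

from iaqrisk import default_config
from iaqrisk.guidelines import default_registry

# Published group summaries: (building_type, compound) -> (n, mean, sd, median)
STRATA = {
    ("dwelling", "formaldehyde"): (383, 131.0, 90.0, 100.0),
    ("office", "formaldehyde"): (406, 85.0, 56.0, 74.0),
    ("dwelling", "benzene"): (379, 17.0, 16.0, 11.0),
    ("office", "benzene"): (375, 30.0, 34.0, 16.0),
}


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def study_config():
    """The packaged default scenario with a fixed test seed."""
    return default_config(seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
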