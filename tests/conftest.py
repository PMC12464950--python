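import numpy as np
import pytest

from fruitlet import synthesis

SEED = 1


@pytest.fixture(scope="session")
def default_cohorts():
    """The four default cultivar x date cohorts at a fixed seed."""
    return synthesis.generate_default_cohorts(SEED)


@pytest.fixture(scope="session")
def noise_free_cohorts():
    return synthesis.generate_default_cohorts(SEED, noise=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
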