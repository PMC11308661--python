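import numpy as np
import pytest

from ticonomics.cea import default_parameters
from ticonomics.cohort import CohortConfig, generate_cohort


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def default_cohort():
    """Survey-sized cohort under baseline settings (fixed seed)."""
    return generate_cohort(CohortConfig(n=144, seed=2))


@pytest.fixture(scope="session")
def big_cohort():
    """Large cohort for Monte-Carlo consistency checks."""
    return generate_cohort(CohortConfig(n=5000, seed=2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
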