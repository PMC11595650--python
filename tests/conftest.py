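import numpy as np
import pytest

from qsea_morph import CohortConfig, sample_cohorts


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    return sample_cohorts(CohortConfig(n_cycles=120, seed=2024))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
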