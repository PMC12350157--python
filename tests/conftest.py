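import numpy as np
import pytest

from pacni import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """80-subject default-condition cohort shared across read-only tests."""
    return simulate_cohort(SyntheticConfig(n_subjects=80, rng_seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
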