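import numpy as np
import pytest

from mhpredict import sample_feature_table
from mhpredict.synthgen import GeneratorConfig


@pytest.fixture(scope="session")
def default_cohort():
    """One 32/11 synthetic cohort at the published calibration."""
    return sample_feature_table(seed=1)


@pytest.fixture(scope="session")
def large_cohort():
    """A large calibrated cohort for moment and power checks."""
    return sample_feature_table(GeneratorConfig(n_group_a=3200, n_group_b=1100, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
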