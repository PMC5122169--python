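import numpy as np
import pytest

from snofamkit.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def dataset_zero_noise():
    """The small study cohort at zero sequence divergence."""
    return simulate_dataset(SimConfig(seed=42, mu=0.0))
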