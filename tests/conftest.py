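import numpy as np
import pytest

import mussdai as m


@pytest.fixture(scope="session")
def default_dataset() -> m.CohortDataset:
    """One full two-cohort trial generated with the default configuration."""
    return m.generate_cohorts(m.GeneratorConfig(seed=1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
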