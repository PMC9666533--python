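import numpy as np
import pytest

from esrstack.synth import generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """60 normal + 4 periodontitis-like synthetic curves (default priors)."""
    return generate_dataset(60, 4, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
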