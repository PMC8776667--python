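import numpy as np
import pytest

from cystct.phantoms import PhantomParams, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight patients per class, two slices each — enough for split/classify tests."""
    return generate_cohort(8, 2, PhantomParams(seed=42))


@pytest.fixture(scope="session")
def noisefree_params():
    return PhantomParams(noise_sigma=0.0, seed=7)
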