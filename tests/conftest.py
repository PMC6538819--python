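import numpy as np
import pytest

from bfda import get_prior


@pytest.fixture(scope="session")
def default_prior():
    """Directional default analysis prior: half-Cauchy, r = sqrt(2)/2."""
    return get_prior("default")


@pytest.fixture(scope="session")
def informed_prior():
    """Directional informed analysis prior: t(0.35, 3, 0.102) truncated at 0."""
    return get_prior("informed")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
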