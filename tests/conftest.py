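import numpy as np
import pytest

from altcushions.model import default_params


@pytest.fixture(scope="session")
def params():
    """Default full-scale parameter set (40x8, pinned, kappa = 31.6)."""
    return default_params()


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down lattice for cheap stochastic tests."""
    return default_params(N_z=10, N_phi=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
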