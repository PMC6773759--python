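import numpy as np
import pytest

from chemopursuit import solve_kernel


@pytest.fixture(scope="session")
def std_kernel():
    """Stationary kernel at the standard attractant parameters
    (D = 6000 μm²/min, k = 0.6/min, r_tar = 10 μm; L_dif = 100 μm)."""
    return solve_kernel(6000.0, 0.6, 10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
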