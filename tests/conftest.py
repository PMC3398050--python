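import numpy as np
import pytest

from homerange import ValueGrid, VOLE_PARAMS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_grid():
    """7x7 grid at the field-site mean habitat value."""
    return ValueGrid(values=np.full((7, 7), 1.64))


@pytest.fixture
def zero_grid():
    return ValueGrid(values=np.zeros((5, 5)))


@pytest.fixture
def vole_params():
    return VOLE_PARAMS


@pytest.fixture
def block_grid():
    """4x4 torus with a single high-value 2x2 block in zero background."""
    vals = np.zeros((4, 4))
    vals[1:3, 1:3] = 10.0
    return ValueGrid(values=vals)
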