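import numpy as np
import pytest

from toasense.spectral import (
    Geometry,
    make_s2_bandset,
    make_uniform_grid,
    make_wavenumber_grid,
)


@pytest.fixture(scope="session")
def wn_grid():
    return make_wavenumber_grid(400, 2500, 15)


@pytest.fixture(scope="session")
def nm_grid():
    return make_uniform_grid(400, 2500, 1.0)


@pytest.fixture(scope="session")
def geom():
    return Geometry()


@pytest.fixture(scope="session")
def s2_bands():
    return make_s2_bandset()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
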