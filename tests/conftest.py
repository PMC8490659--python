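import numpy as np
import pytest

import uvtrace as uv

SMALL_SHAPE = (256, 128)  # keeps unit tests fast; geometry scales with shape


@pytest.fixture(scope="session")
def small_atlas():
    return uv.default_atlas(SMALL_SHAPE)


@pytest.fixture(scope="session")
def small_design():
    return uv.default_design(SMALL_SHAPE, seed=1)


@pytest.fixture(scope="session")
def small_truth(small_design):
    """Default synthetic study at reduced raster size."""
    return uv.simulate_transfer(small_design, uv.default_kernels(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
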