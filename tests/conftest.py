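import numpy as np
import pytest

from onsdnet import (NetConfig, ONSDNet, PhantomParams, generate_phantom)


@pytest.fixture(scope="session")
def tiny_net():
    """Width-reduced network for CPU tests (64 x 64 inputs are enough)."""
    return ONSDNet(NetConfig(width=4, seed=0))


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomParams(), seed=1)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, blur-free phantom: piecewise-constant image."""
    return generate_phantom(
        PhantomParams(speckle_scale=0.0, blur_sigma=0.0), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
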