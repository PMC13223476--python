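import numpy as np
import pytest

from grmaseg import NetConfig, PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One 32x32x8 phantom with two small low-contrast lesions."""
    cfg = PhantomConfig(shape=(32, 32, 8), n_lesions=2, radius_range=(2.0, 3.5), seed=7)
    return make_phantom(cfg)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """Width-4 network config: smallest architecture exercising every module."""
    return NetConfig(base_channels=4, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
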