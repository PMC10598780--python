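import numpy as np
import pytest

from retro_t2.config import RunConfig
from retro_t2.io_core import ImageVolume
from retro_t2.phantom import generate_phantom

TE_LIST = [10.5, 21.0, 31.5, 42.0, 52.5, 63.0, 73.5, 84.0]


@pytest.fixture(scope="session")
def small_cfg() -> RunConfig:
    """Desk-scale config with a small grid for fast unit tests."""
    cfg = RunConfig()
    cfg.phantom.grid = [64, 64, 4]
    return cfg


@pytest.fixture(scope="session")
def small_subject(small_cfg):
    return generate_phantom(small_cfg.phantom, seed=7, subject_id="sub-test")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def mono_exp_echoes(s0, t2, te_list, shape=(2, 2, 1)):
    """Noiseless mono-exponential echo train as ImageVolumes."""
    return [ImageVolume(np.full(shape, s0 * np.exp(-te / t2))) for te in te_list]
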