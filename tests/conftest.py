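import numpy as np
import pytest

from limbfuse.gaitsim import GaitProfile, SimConfig, make_dataset


@pytest.fixture(scope="session")
def bench_dataset():
    """The default seeded synthetic benchmark: 10 s walk at 1111 Hz / 30 fps,
    64x64 depth, seed 1 (~290 synchronized records)."""
    return make_dataset(GaitProfile(), SimConfig(duration_s=10.0, seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast low-resolution capture for plumbing tests."""
    return make_dataset(GaitProfile(), SimConfig(duration_s=4.0, seed=3,
                                                 depth_resolution=(32, 32)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
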