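import numpy as np
import pytest

from pmmorph.core import BinaryMask, ScalarVolume, VoxelGrid
from pmmorph.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom_sample():
    """One default 64^3 phantom shared across tests (read-only)."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_pair(phantom_sample):
    return (phantom_sample.t1, phantom_sample.t2)


@pytest.fixture
def grid8():
    return VoxelGrid((8, 8, 8), (0.5, 0.5, 0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_scalar(grid: VoxelGrid, rng: np.random.Generator) -> ScalarVolume:
    return ScalarVolume(grid, rng.random(grid.dims).astype(np.float32))


def random_mask(grid: VoxelGrid, rng: np.random.Generator, p: float = 0.5) -> BinaryMask:
    return BinaryMask(grid, (rng.random(grid.dims) < p).astype(np.int32))
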