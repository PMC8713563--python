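import numpy as np
import pytest

from icdpipe.images import Mask3D, Volume4D, make_affine
from icdpipe.preprocess import MotionTrace
from icdpipe.simulate import SimDesign, default_geometry, simulate_covariates


@pytest.fixture(scope="session")
def default_design() -> SimDesign:
    return SimDesign(seed=7)


@pytest.fixture(scope="session")
def geometry(default_design):
    return default_geometry(default_design)


@pytest.fixture(scope="session")
def covariates_200():
    return simulate_covariates(SimDesign(n_subjects=200, seed=1))


def make_volume(data: np.ndarray, voxel_mm: float = 3.0, tr: float = 3.0) -> Volume4D:
    return Volume4D(data, make_affine(voxel_mm), tr)


def zero_motion(n_frames: int) -> MotionTrace:
    return MotionTrace(np.zeros((n_frames, 6)))


def box_mask(shape, voxel_mm: float = 3.0, full: bool = True) -> Mask3D:
    m = np.ones(shape, dtype=bool) if full else np.zeros(shape, dtype=bool)
    return Mask3D(m, make_affine(voxel_mm))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
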