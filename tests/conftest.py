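import numpy as np
import pytest

from midfc.cohort import (
    ConnectivityDesign,
    SubjectRecord,
    make_seed_masks,
    make_tissue_masks,
)
from midfc.volume import Bold4D, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid((20, 24, 20))


@pytest.fixture(scope="session")
def seed_masks(grid):
    return make_seed_masks(grid, seed=1)


@pytest.fixture(scope="session")
def tissues(grid):
    return make_tissue_masks(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def record():
    return SubjectRecord(subject_id="sub0000_Beijing_Zang", age=25.0,
                         sex="female", site="Beijing_Zang", tr=2.0,
                         n_timepoints=225)


@pytest.fixture
def null_design():
    """Zero planted effect, no nuisance components."""
    return ConnectivityDesign(
        base_rho=0.0,
        nuisance_amplitudes={"global": 0.0, "white_matter": 0.0,
                             "ventricle": 0.0},
    )


def make_bold(data, tr=2.0, voxel=3.0):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return Bold4D(data=np.asarray(data, dtype=float), affine=affine, tr=tr)


@pytest.fixture
def small_series(rng):
    """A tiny random 4D series: 5x5x5 voxels, 40 frames."""
    return make_bold(100.0 + rng.standard_normal((5, 5, 5, 40)))
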