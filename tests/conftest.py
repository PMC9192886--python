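import numpy as np
import pytest

from spectboost.phantom_sim import AcquisitionSpec, PhantomSpec, make_paired_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def desk_phantom_spec():
    """Phantom on a coarse 64x64 grid the full cylinder still fits into."""
    return PhantomSpec(grid_shape=(32, 64, 64), voxel_size_mm=6.0)


@pytest.fixture(scope="session")
def fast_acq():
    return AcquisitionSpec(seconds_per_projection=3.0, psf_fwhm_mm=12.0, rng_seed=101)


@pytest.fixture(scope="session")
def std_acq():
    return AcquisitionSpec(seconds_per_projection=20.0, psf_fwhm_mm=12.0, rng_seed=202)


@pytest.fixture(scope="session")
def desk_case(fast_acq, std_acq):
    """One simulated subject quadruplet on the desk grid (session-cached)."""
    return make_paired_dataset(fast_acq, std_acq, seed=5, n_subjects=1,
                               subject_grid_shape=(32, 64, 64), subject_voxel_mm=6.0,
                               keep_activity=True)[0]
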