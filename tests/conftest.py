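import pytest

from weakdecon import (OpticalParams, SimConfig, born_wolf_psf,
                       effective_confocal_psf)

SMALL_GRID = (32, 32, 8)
SMALL_PITCH = (80.0, 80.0, 250.0)


@pytest.fixture(scope="session")
def small_params_ex():
    return OpticalParams(1.4, 1.5, 488.0, SMALL_PITCH, SMALL_GRID)


@pytest.fixture(scope="session")
def small_params_em():
    return OpticalParams(1.4, 1.5, 510.0, SMALL_PITCH, SMALL_GRID)


@pytest.fixture(scope="session")
def small_psf_ex(small_params_ex):
    return born_wolf_psf(small_params_ex)


@pytest.fixture(scope="session")
def small_psf_em(small_params_em):
    return born_wolf_psf(small_params_em)


@pytest.fixture(scope="session")
def small_psf_eff(small_psf_ex, small_psf_em):
    return effective_confocal_psf(small_psf_ex, small_psf_em)


@pytest.fixture(scope="session")
def small_sim_config():
    """A scaled-down lattice simulation that runs in well under a second."""
    return SimConfig(grid_dims=(80, 80, 16), xy_spacing=20, array_shape=(3, 3), seed=7)


@pytest.fixture(scope="session")
def default_psf():
    """Effective confocal PSF on the full default 200x200x40 grid (built once)."""
    kwargs = dict(numerical_aperture=1.4, refractive_index=1.5,
                  voxel_pitch=(80.0, 80.0, 250.0), grid_dims=(200, 200, 40))
    ex = born_wolf_psf(OpticalParams(wavelength=488.0, **kwargs))
    em = born_wolf_psf(OpticalParams(wavelength=510.0, **kwargs))
    return effective_confocal_psf(ex, em)
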