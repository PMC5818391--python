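"""Shared fixtures.

Rasterization of the default phantom onto the preset grids is the expensive
step, so fraction maps and noiseless base images are session-scoped and
shared across test modules.
"""

from dataclasses import replace

import numpy as np
import pytest

import nemaquant as nq


@pytest.fixture(scope="session")
def geometry():
    return nq.default_nema_geometry()


@pytest.fixture(scope="session")
def pet_setup():
    grid, acq = nq.preset("pet-ga68")
    return grid, acq


@pytest.fixture(scope="session")
def spect_setup():
    grid, acq = nq.preset("spect-in111")
    return grid, acq


@pytest.fixture(scope="session")
def pet_fractions(geometry, pet_setup):
    grid, _ = pet_setup
    return nq.voxelize(geometry, grid, subsampling=2)


@pytest.fixture(scope="session")
def spect_fractions(geometry, spect_setup):
    grid, _ = spect_setup
    return nq.voxelize(geometry, grid, subsampling=2)


@pytest.fixture(scope="session")
def nb_activity():
    return nq.ActivityConfig.from_sbr("NB", 20.0)


@pytest.fixture(scope="session")
def pet_nb_noiseless(geometry, pet_setup, pet_fractions, nb_activity):
    """Noiseless NB PET-like image without the positron-range surrogate."""
    grid, acq = pet_setup
    acq = replace(acq, noise=nq.NoiseModel("none"), extra_blur_fwhm=0.0)
    return nq.simulate(geometry, grid, nb_activity, acq, fractions=pet_fractions)


@pytest.fixture(scope="session")
def spect_calibration(spect_setup):
    """Noiseless sensitivity calibration from a uniformly filled phantom."""
    grid, acq = spect_setup
    acq0 = replace(acq, noise=nq.NoiseModel("none"))
    conc = 5.0  # kBq/mL
    image = nq.simulate(nq.uniform_geometry(), grid, nq.ActivityConfig(0.0, conc), acq0)
    return nq.sensitivity_factor(image, conc / 1000.0, acq.duration, grid)


def toy_image(values, spacing=(1.0, 1.0, 1.0), unit="kBq/mL"):
    values = np.asarray(values, dtype=float)
    grid = nq.GridSpec.centered(values.shape, spacing)
    return nq.ImageVolume(values=values, grid=grid, value_unit=unit)
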