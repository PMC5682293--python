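import numpy as np
import pytest
from hypothesis import settings

from mirrorspim.forward_model import AcquisitionPlan, ImagingOperator
from mirrorspim.geometry import MirrorGeometry
from mirrorspim.optics import LightSheetSpec, ObjectiveSpec, make_detection_psf
from mirrorspim.volume import GridSpec, Volume

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    """12x8x12 grid at 0.1 um pitch — the dense-oracle problem size."""
    return GridSpec((12, 8, 12), (0.1, 0.1, 0.1))


@pytest.fixture(scope="session")
def gaussian_psf(small_grid):
    psf_grid = GridSpec((7, 5, 5), small_grid.pitch)
    return make_detection_psf(ObjectiveSpec(na=0.8), 0.525, psf_grid,
                              "gaussian", strict=False)


@pytest.fixture(scope="session")
def mirror45():
    return MirrorGeometry(theta_deg=45.0, reflectivity=1.0)


@pytest.fixture(scope="session")
def thin_sheet():
    return LightSheetSpec(fwhm_um=0.4)


@pytest.fixture()
def operator(gaussian_psf, thin_sheet, mirror45, small_grid):
    """Fresh shift-varying operator (own convolution counter) per test."""
    return ImagingOperator(gaussian_psf, thin_sheet, mirror45, small_grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170913)
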