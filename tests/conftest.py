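import numpy as np
import pytest

from mrtplan import BeamGeometry, generate_spectrum, make_slab_phantom
from mrtplan.microbeam import electron_kernel


@pytest.fixture(scope="session")
def geometry():
    """Reference setup: sd 212 mm, 30/400 um collimator, sigma 0.58 mm."""
    return BeamGeometry()


@pytest.fixture(scope="session")
def spectrum():
    return generate_spectrum(225.0, filtration_mm_al=1.0)


@pytest.fixture(scope="session")
def e_eff(spectrum):
    return spectrum.effective_energy_kev()


@pytest.fixture(scope="session")
def kernel_pmma(spectrum):
    return electron_kernel(spectrum, density=1.19)


@pytest.fixture(scope="session")
def pmma_slab_small():
    """20 mm deep PMMA slab used by the transport self-consistency tests."""
    return make_slab_phantom((20.0, 20.0, 20.0), "pmma", 1.0)


@pytest.fixture()
def um_grid():
    """+-1 mm lateral grid at 1 um pitch (mm units)."""
    return np.arange(-1000, 1001) * 1e-3
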