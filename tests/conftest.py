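import numpy as np
import pytest

from trimodal.forward import AcquisitionSpec, TransducerSpec
from trimodal.phantom import Background, GridSpec, make_phantom
from trimodal.spectra import SpectraTable


@pytest.fixture(scope="session")
def spectra():
    return SpectraTable.default()


@pytest.fixture(scope="session")
def tx():
    return TransducerSpec()


@pytest.fixture()
def quiet_acq():
    return AcquisitionSpec(noise_rms=0.0, seed=0)


@pytest.fixture()
def slab_grid():
    """Single-slice (2.5-D) phantom grid, 8 x 20 mm at 0.125 mm voxels."""
    return GridSpec((64, 1, 160), 0.125)


@pytest.fixture()
def empty_slab(slab_grid):
    return make_phantom([], slab_grid, Background(), seed=0)


def point_phantom(grid, points, species="ICG", value=1e-5):
    """Phantom with single-voxel concentration spikes at (x, z) mm points."""
    phantom = make_phantom([], grid, Background(), seed=0)
    for sx, sz in points:
        ix = int(np.argmin(np.abs(grid.x_mm - sx)))
        iz = int(np.argmin(np.abs(grid.z_mm - sz)))
        phantom.conc[species][ix, 0, iz] = value
    return phantom
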