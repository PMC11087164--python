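import numpy as np
import pytest

import arccheck_qa as aq
from arccheck_qa.grids import Grid3D


@pytest.fixture(scope="session")
def array():
    return aq.build_detector_array()


@pytest.fixture(scope="session")
def slab_grid():
    """Coarse grid covering the phantom cross-section and the EEDR diodes (|z| <= 20)."""
    return Grid3D.centered((280.0, 280.0, 40.0), (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def five_layer_volume(slab_grid):
    rings = aq.default_rings()
    structures = aq.build_structures(rings, grid=slab_grid)
    return aq.voxelize_red(structures, aq.default_red_table(rings), slab_grid)


@pytest.fixture(scope="session")
def engine_config():
    return aq.EngineConfig()


@pytest.fixture(scope="session")
def calibration_beam():
    return aq.BeamSpec()  # 10 x 10 cm^2, gantry 0, 200 MU


@pytest.fixture(scope="session")
def five_layer_detector_doses(five_layer_volume, calibration_beam, engine_config, array):
    return aq.detector_doses(five_layer_volume, calibration_beam, engine_config, array)


def uniform_dose_grid(value=1.0, extent=(280.0, 280.0, 240.0), spacing=8.0):
    grid = Grid3D.centered(extent, (spacing, spacing, spacing))
    return aq.DoseGrid(grid, np.full((grid.shape[2], grid.shape[1], grid.shape[0]), float(value)))


@pytest.fixture
def uniform_grid():
    return uniform_dose_grid(1.0)
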