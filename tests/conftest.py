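import dataclasses

import numpy as np
import pytest

import voxdose as vd
from voxdose.phantom import build_phantom, example_study_phantom


@pytest.fixture(scope="session")
def lu177():
    return vd.load_nuclide("lu177")


@pytest.fixture(scope="session")
def lu177_beta(lu177):
    """Electron-only variant: the local-beta truth ledger is exact for it."""
    return dataclasses.replace(lu177, photon_lines=())


@pytest.fixture(scope="session")
def y90():
    return vd.load_nuclide("y90")


@pytest.fixture(scope="session")
def config():
    return vd.DosimetryConfig()


@pytest.fixture(scope="session")
def study(lu177):
    """Reference synthetic study at test scale, built once per session."""
    spec = example_study_phantom(nuclide=lu177)
    return spec, build_phantom(spec, seed=0)


def uniform_volume(shape=(8, 8, 8), value=1.0, quantity="doserate_Gy_h", voxel_mm=4.795):
    grid = vd.VoxelGrid(shape=shape, voxel_size_mm=voxel_mm)
    return vd.ScalarVolume(grid, np.full(shape, float(value)), quantity)
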