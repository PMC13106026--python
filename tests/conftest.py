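import numpy as np
import pytest

import decbct
from decbct.acquisition import Geometry
from decbct.decomposition import DualEnergyModel
from decbct.phantom import PhantomSpec
from decbct.reconstruction import ReconGrid


@pytest.fixture(scope="session")
def spectrum_80():
    return decbct.generate_spectrum(80.0)


@pytest.fixture(scope="session")
def spectrum_140():
    return decbct.generate_spectrum(140.0)


@pytest.fixture(scope="session")
def de_model(spectrum_80, spectrum_140):
    return DualEnergyModel(spectrum_80, spectrum_140)


@pytest.fixture(scope="session")
def small_geometry():
    """64-column fan geometry covering the 20 cm phantom, for fast tests."""
    return Geometry(detector_columns=64, detector_pixel_mm=6.4)


@pytest.fixture(scope="session")
def small_grid():
    return ReconGrid(voxel_mm=3.5, nx=64, ny=64)


@pytest.fixture(scope="session")
def water_phantom():
    return PhantomSpec(outer_radius=100.0, background_material="water", inserts=())


def water_sinogram(geometry, angles, energy=60.0):
    """Noiseless monoenergetic sinogram of the 20 cm water cylinder."""
    spec = PhantomSpec(outer_radius=100.0, background_material="water", inserts=())
    mu = decbct.linear_attenuation("water", energy)
    sino = np.stack(
        [mu * decbct.raytrace(spec, geometry, a)["water"] for a in angles]
    )
    return sino
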