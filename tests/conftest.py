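import numpy as np
import pytest

from retmetrics.geometry import ScanGeometry
from retmetrics.phantom import RenderParams, SurfaceModelParams, \
    generate_surfaces, render_cube
from retmetrics.surfaces import BoundarySurfaces

# A cube short along y and z keeps rendering cheap; the full 512 A-scan
# lateral resolution is kept where the dynamic-programming step limit
# matters (the foveal pit slope is resolution-dependent).
SMALL_GEO = ScanGeometry(n_ascans_x=96, n_bscans_y=12, n_axial_z=320)
NATIVE_X_GEO = ScanGeometry(n_ascans_x=512, n_bscans_y=8, n_axial_z=320)


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    return SMALL_GEO


@pytest.fixture(scope="session")
def native_geometry() -> ScanGeometry:
    return NATIVE_X_GEO


@pytest.fixture(scope="session")
def truth_native(native_geometry):
    return generate_surfaces(native_geometry, SurfaceModelParams(seed=0))


@pytest.fixture(scope="session")
def noiseless_cube(truth_native, native_geometry):
    return render_cube(truth_native, native_geometry,
                       RenderParams(speckle_contrast=0.0,
                                    additive_noise_sd=0.0))


def flat_surfaces(geometry: ScanGeometry, ilm: float, onl: float,
                  ez: float, rpe: float) -> BoundarySurfaces:
    """Four constant-depth surfaces (axial samples)."""
    shape = geometry.enface_shape
    pos = np.stack([np.full(shape, v, dtype=float)
                    for v in (ilm, onl, ez, rpe)])
    return BoundarySurfaces(pos, geometry)


def random_valid_surfaces(geometry: ScanGeometry, seed: int) -> BoundarySurfaces:
    """Random surfaces satisfying the ordering invariant (sorted per cell)."""
    rng = np.random.default_rng(seed)
    raw = rng.uniform(10, geometry.n_axial_z - 10,
                      size=(4,) + geometry.enface_shape)
    return BoundarySurfaces(np.sort(raw, axis=0), geometry)
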