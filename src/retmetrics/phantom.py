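"""Synthetic macular-cube phantom: ground-truth surfaces and rendered volumes.

The phantom emulates the anatomy the segmentation targets: a smooth retina
whose inner layers (ILM to the proximal ONL/HFL boundary) thin toward a
radially symmetric foveal pit, a thicker nasal inner retina (the nerve
fiber layer is thicker toward the optic disc), a constant-thickness
photoreceptor outer-segment band (EZ to RPE), speckle-like multiplicative
noise and vessel shadow columns. It exists to provide exact ground truth
for the boundary segmenter and the metric engine; it does not model real
OCT speckle statistics or beam optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cube import MacularCube
from .geometry import ScanGeometry
from .surfaces import BoundarySurfaces, OrderingError

__all__ = [
    "SurfaceModelParams",
    "RenderParams",
    "generate_surfaces",
    "render_cube",
]


@dataclass(frozen=True)
class SurfaceModelParams:
    """Ground-truth anatomy of the phantom.

    All thicknesses in micrometres; lateral lengths in millimetres. The
    foveal pit is a Gaussian dip of depth ``pit_depth`` and e-folding radius
    ``pit_radius`` subtracted from the inner-retina thickness, so the
    central inner retina measures
    ``inner_thickness_peripheral - pit_depth``. ``nasal_temporal_asymmetry``
    is the extra inner thickness at the +x scan edge (mirrored as a deficit
    at -x), applied as a linear gradient. ``ez_rpe_thickness`` is constant:
    the pit shapes only the inner layers.
    """

    base_depth_ilm: float = 120.0
    inner_thickness_peripheral: float = 190.0
    pit_depth: float = 168.5
    pit_radius: float = 0.34
    pit_center_offset: tuple[float, float] = (0.0, 0.0)
    outer_thickness: float = 160.0
    ez_rpe_thickness: float = 50.0
    nasal_temporal_asymmetry: float = 40.0
    surface_smoothness: float = 0.5
    perturbation_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.inner_thickness_peripheral, self.outer_thickness,
               self.ez_rpe_thickness) < 0:
            raise ValueError("thicknesses must be >= 0")
        if self.pit_radius <= 0:
            raise ValueError("pit_radius must be > 0")
        if self.pit_depth >= self.inner_thickness_peripheral + self.outer_thickness:
            raise ValueError(
                "pit_depth must be smaller than the total retinal thickness"
            )


@dataclass(frozen=True)
class RenderParams:
    """Rendering model for the phantom cube.

    ``layer_reflectivities`` are the mean intensities of the six bands
    (vitreous, inner retina, ONL/HFL, EZ-to-RPE, RPE, choroid); the bright
    RPE band extends ``rpe_band_um`` below the proximal RPE edge before the
    choroid. ``speckle_contrast`` is the sd/mean of the per-voxel
    multiplicative (gamma) noise field. Vessel shadows multiply all
    intensity below the ILM inside a lateral disc by ``attenuation_factor``.
    """

    layer_reflectivities: tuple[float, ...] = (0.05, 0.40, 0.12, 0.60, 0.85, 0.30)
    rpe_band_um: float = 15.0
    speckle_contrast: float = 0.3
    vessel_shadow_columns: tuple[tuple[float, float, float, float], ...] = ()
    additive_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_reflectivities) != 6:
            raise ValueError("layer_reflectivities must list six bands")
        if min(self.layer_reflectivities) < 0:
            raise ValueError("reflectivities must be >= 0")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle_contrast must be in [0, 1]")
        for col in self.vessel_shadow_columns:
            if not 0.0 <= col[3] <= 1.0:
                raise ValueError("attenuation_factor must be in [0, 1]")


def _smooth_field(rng: np.random.Generator, geometry: ScanGeometry,
                  correlation_mm: float, sd_um: float) -> np.ndarray:
    """Zero-mean random en face field with the given sd and lateral scale."""
    if sd_um == 0:
        return np.zeros(geometry.enface_shape)
    noise = rng.standard_normal(geometry.enface_shape)
    sig_x = max(correlation_mm / geometry.pitch_x, 1e-6)
    sig_y = max(correlation_mm / geometry.pitch_y, 1e-6)
    smooth = ndimage.gaussian_filter(noise, sigma=(sig_x, sig_y), mode="nearest")
    s = smooth.std()
    if s < 1e-12:  # fully flat after smoothing
        return np.zeros(geometry.enface_shape)
    return smooth * (sd_um / s)


def generate_surfaces(geometry: ScanGeometry,
                      params: SurfaceModelParams) -> BoundarySurfaces:
    """Ground-truth ILM/ONLHFL/EZ/RPE surfaces on the full en face grid.

    Deterministic for a fixed ``params.seed``. Raises :class:`OrderingError`
    (naming the offending en face position) if the parameter combination
    produces crossing surfaces or positions outside the axial range.
    """
    rng = np.random.default_rng(params.seed)
    x = geometry.x_mm()[:, None]
    y = geometry.y_mm()[None, :]

    cx, cy = params.pit_center_offset
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    pit = params.pit_depth * np.exp(-r2 / (2.0 * params.pit_radius ** 2))

    tilt = params.nasal_temporal_asymmetry * (x / (geometry.lateral_extent_x / 2.0))
    inner = params.inner_thickness_peripheral + tilt - pit
    inner = inner + _smooth_field(rng, geometry, params.surface_smoothness,
                                  params.perturbation_sd / 2.0)

    onl_ez = params.outer_thickness - params.ez_rpe_thickness
    onl_ez = onl_ez + _smooth_field(rng, geometry, params.surface_smoothness,
                                    params.perturbation_sd / 2.0)

    base = params.base_depth_ilm + _smooth_field(
        rng, geometry, params.surface_smoothness, params.perturbation_sd)

    # The retina is anchored at a flat-ish RPE: the foveal pit is a dip of
    # the ILM (thinned inner layers), not a bump of the outer surfaces.
    scale = geometry.axial_scale
    rpe = (base + params.inner_thickness_peripheral + onl_ez
           + params.ez_rpe_thickness) / scale
    ez = rpe - params.ez_rpe_thickness / scale
    onlhfl = ez - onl_ez / scale
    ilm = onlhfl - inner / scale

    surfaces = BoundarySurfaces(np.stack([ilm, onlhfl, ez, rpe]), geometry)
    surfaces.validate()
    return surfaces


def render_cube(surfaces: BoundarySurfaces, geometry: ScanGeometry,
                render: RenderParams, *, laterality: str = "OD",
                signal_strength: int = 10,
                subject_id: str = "phantom") -> MacularCube:
    """Render a macular cube from boundary surfaces.

    The noise-free expected intensity is piecewise constant between the
    rounded surface positions at the configured reflectivities; vessel
    shadows then attenuate everything below the ILM in their columns, and
    multiplicative speckle plus additive Gaussian noise are applied per
    voxel. Deterministic for a fixed ``render.seed``.
    """
    if surfaces.geometry.cube_shape != geometry.cube_shape:
        raise ValueError("surfaces are not defined on the requested geometry")
    rng = np.random.default_rng(render.seed)
    nz = geometry.n_axial_z
    z = np.arange(nz)[None, None, :]

    refl = np.asarray(render.layer_reflectivities, dtype=np.float32)
    rpe_band = render.rpe_band_um / geometry.axial_scale

    band = np.zeros(geometry.cube_shape, dtype=np.uint8)
    for k in range(4):
        band += (z >= np.round(surfaces.positions[k])[:, :, None]).astype(np.uint8)
    band += (z >= np.round(surfaces.positions[3] + rpe_band)[:, :, None]).astype(np.uint8)
    intensity = refl[band]

    if render.vessel_shadow_columns:
        x = geometry.x_mm()[:, None]
        y = geometry.y_mm()[None, :]
        ilm = np.round(surfaces["ILM"])[:, :, None]
        below = z >= ilm
        for (sx, sy, radius, att) in render.vessel_shadow_columns:
            disc = (x - sx) ** 2 + (y - sy) ** 2 <= radius ** 2
            mask = disc[:, :, None] & below
            intensity[mask] *= att

    c = render.speckle_contrast
    if c > 0:
        speckle = rng.gamma(shape=1.0 / c ** 2, scale=c ** 2,
                            size=geometry.cube_shape).astype(np.float32)
        intensity = intensity * speckle
    if render.additive_noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, render.additive_noise_sd, size=geometry.cube_shape
        ).astype(np.float32)
    np.clip(intensity, 0.0, None, out=intensity)

    return MacularCube(intensity, geometry, laterality=laterality,
                       signal_strength=signal_strength, subject_id=subject_id)
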