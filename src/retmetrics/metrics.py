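"""Per-eye layer metrics: thickness maps, point thicknesses, areas, volumes
and en face EZ attenuation percentages.

Conventions
-----------
Thickness between two boundaries is (deeper - shallower) position times the
axial scale, in µm. The foveal B-scan area integrates the thickness profile
over the full lateral extent (piecewise linear between cell-centered
A-scans, constant over the two half-cell margins), which reduces to
pitch x sum(thickness). Volumes use midpoint quadrature, cell area x
thickness. En face attenuation is the percentage of all en face cells with
EZ-RPE thickness below 20 µm; total loss is the percentage at zero (up to
half an axial sample, guarding fractional-surface quantization).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
from scipy import ndimage

from .geometry import ScanGeometry
from .surfaces import BoundarySurfaces, SURFACE_NAMES

__all__ = [
    "LAYER_PAIRS",
    "ThicknessMap",
    "FoveaLocation",
    "AnalysisConfig",
    "EyeMetrics",
    "thickness_map",
    "locate_fovea",
    "point_thickness",
    "bscan_area",
    "layer_volume",
    "enface_attenuation",
    "compute_eye_metrics",
]

#: layer pair -> (shallow surface, deep surface). The inner retina runs
#: from the ILM to the proximal ONL/HFL boundary (the distal OPL edge),
#: hence the ILM-OPL label for the ILM-ONLHFL pair.
LAYER_PAIRS: dict[str, tuple[str, str]] = {
    "ILM-RPE": ("ILM", "RPE"),
    "ILM-OPL": ("ILM", "ONLHFL"),
    "ONLHFL-RPE": ("ONLHFL", "RPE"),
    "EZ-RPE": ("EZ", "RPE"),
    "ONLHFL-EZ": ("ONLHFL", "EZ"),
}


@dataclass
class ThicknessMap:
    """En face map of a layer-pair thickness in µm."""

    values: np.ndarray
    layer_pair: str
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.enface_shape:
            raise ValueError("map shape does not match geometry")
        if self.layer_pair not in LAYER_PAIRS:
            raise ValueError(f"unknown layer pair {self.layer_pair!r}")
        if self.values.min() < -1e-9:
            raise ValueError("thickness map contains negative values")


@dataclass(frozen=True)
class FoveaLocation:
    """Foveal center on the en face grid."""

    x_index: int
    y_index: int
    x_mm: float
    y_mm: float
    flagged: bool = False  # set when no interior minimum existed


@dataclass(frozen=True)
class AnalysisConfig:
    """Metric-engine settings.

    ``od_nasal_side`` states which lateral end of a right-eye (OD) B-scan
    is nasal; left eyes (OS) are mirrored. This is an acquisition
    convention that must be set consciously for real exports.
    """

    attenuation_threshold_um: float = 20.0
    loss_threshold_um: float = 0.0
    juxtafoveal_offset_mm: float = 1.0
    od_nasal_side: str = "right"
    fovea_smoothing_mm: float = 0.25
    fovea_search_halfwidth_mm: float = 1.5

    def __post_init__(self) -> None:
        if not 0 <= self.loss_threshold_um < self.attenuation_threshold_um:
            raise ValueError(
                "need 0 <= loss_threshold_um < attenuation_threshold_um")
        if self.od_nasal_side not in ("left", "right"):
            raise ValueError("od_nasal_side must be 'left' or 'right'")


@dataclass
class EyeMetrics:
    """One eye's full metric record (units in the field names)."""

    ilm_rpe_central_um: float = np.nan
    ilm_rpe_nasal_um: float = np.nan
    ilm_rpe_temporal_um: float = np.nan
    ilm_opl_central_um: float = np.nan
    ilm_opl_nasal_um: float = np.nan
    ilm_opl_temporal_um: float = np.nan
    onl_rpe_central_um: float = np.nan
    onl_rpe_nasal_um: float = np.nan
    onl_rpe_temporal_um: float = np.nan
    ez_rpe_central_um: float = np.nan
    ez_rpe_nasal_um: float = np.nan
    ez_rpe_temporal_um: float = np.nan
    onl_ez_area_mm2: float = np.nan
    onl_ez_volume_mm3: float = np.nan
    ez_rpe_area_mm2: float = np.nan
    ez_rpe_volume_mm3: float = np.nan
    onl_rpe_area_mm2: float = np.nan
    onl_rpe_volume_mm3: float = np.nan
    ez_attenuation_pct: float = np.nan
    ez_total_loss_pct: float = np.nan
    fovea_flagged: bool = False

    def __post_init__(self) -> None:
        a, l = self.ez_attenuation_pct, self.ez_total_loss_pct
        if np.isfinite(a) and np.isfinite(l):
            if not 0.0 <= l <= a <= 100.0:
                raise ValueError(
                    f"need 0 <= total loss ({l}) <= attenuation ({a}) <= 100")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def metric_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(cls) if f.name != "fovea_flagged")


# ---------------------------------------------------------------------------

def thickness_map(surfaces: BoundarySurfaces, layer_pair: str) -> ThicknessMap:
    """Cell-wise (deep - shallow) x axial_scale, in µm; never negative."""
    try:
        top, bottom = LAYER_PAIRS[layer_pair]
    except KeyError:
        raise ValueError(
            f"unknown layer pair {layer_pair!r}; "
            f"known: {sorted(LAYER_PAIRS)}") from None
    values = (surfaces[bottom] - surfaces[top]) * surfaces.geometry.axial_scale
    return ThicknessMap(np.maximum(values, 0.0), layer_pair, surfaces.geometry)


def locate_fovea(surfaces: BoundarySurfaces,
                 config: AnalysisConfig | None = None) -> FoveaLocation:
    """Foveal center: minimum of the smoothed inner-retina thickness map.

    The search is restricted to the central window (default 3x3 mm). Ties
    break toward the cube center, then smaller x, then smaller y. A map
    with no interior structure (flat) returns the cube center, flagged.
    """
    if config is None:
        config = AnalysisConfig()
    geo = surfaces.geometry
    inner = thickness_map(surfaces, "ILM-OPL").values
    sig = (config.fovea_smoothing_mm / geo.pitch_x,
           config.fovea_smoothing_mm / geo.pitch_y)
    smooth = ndimage.gaussian_filter(inner, sigma=sig, mode="nearest")

    x_mm, y_mm = geo.x_mm(), geo.y_mm()
    hw = config.fovea_search_halfwidth_mm
    in_x = np.abs(x_mm) <= hw
    in_y = np.abs(y_mm) <= hw
    sub = smooth[np.ix_(in_x, in_y)]
    if np.ptp(sub) < 1e-9:
        xi = int(np.argmin(np.abs(x_mm)))
        yi = int(np.argmin(np.abs(y_mm)))
        return FoveaLocation(xi, yi, float(x_mm[xi]), float(y_mm[yi]),
                             flagged=True)

    minval = sub.min()
    cand = np.argwhere(sub <= minval + 1e-12)
    xs = np.where(in_x)[0][cand[:, 0]]
    ys = np.where(in_y)[0][cand[:, 1]]
    r2 = x_mm[xs] ** 2 + y_mm[ys] ** 2
    order = np.lexsort((ys, xs, np.round(r2, 9)))
    xi, yi = int(xs[order[0]]), int(ys[order[0]])
    return FoveaLocation(xi, yi, float(x_mm[xi]), float(y_mm[yi]))


def _nasal_sign(laterality: str, config: AnalysisConfig) -> float:
    """+1 if nasal lies toward +x for this eye, else -1."""
    sign = 1.0 if config.od_nasal_side == "right" else -1.0
    if laterality == "OS":
        sign = -sign
    elif laterality != "OD":
        raise ValueError(f"unknown laterality {laterality!r}")
    return sign


def point_thickness(tmap: ThicknessMap, fovea: FoveaLocation,
                    offset_mm: float, laterality: str,
                    config: AnalysisConfig | None = None) -> float:
    """Thickness on the foveal B-scan at a signed nasal offset from the fovea.

    ``offset_mm`` is in the nasal-positive convention: +1.0 samples 1 mm
    nasal, -1.0 samples 1 mm temporal; the x direction of "nasal" follows
    the eye's laterality and ``config.od_nasal_side``. Values are linearly
    interpolated between A-scan centers.
    """
    if config is None:
        config = AnalysisConfig()
    geo = tmap.geometry
    x_target = fovea.x_mm + _nasal_sign(laterality, config) * offset_mm
    x_grid = geo.x_mm()
    if not x_grid[0] - 1e-9 <= x_target <= x_grid[-1] + 1e-9:
        raise ValueError(
            f"offset {offset_mm} mm falls at x = {x_target:.2f} mm, outside "
            f"the sampled extent [{x_grid[0]:.2f}, {x_grid[-1]:.2f}] mm")
    profile = tmap.values[:, fovea.y_index]
    return float(np.interp(x_target, x_grid, profile))


def bscan_area(surfaces: BoundarySurfaces, layer_pair: str,
               b_scan_index: int, geometry: ScanGeometry | None = None) -> float:
    """Area (mm^2) of a layer pair on one B-scan across the lateral extent."""
    geo = geometry if geometry is not None else surfaces.geometry
    if not 0 <= b_scan_index < geo.n_bscans_y:
        raise IndexError(f"B-scan index {b_scan_index} out of range")
    profile_mm = thickness_map(surfaces, layer_pair).values[:, b_scan_index] / 1000.0
    return float(geo.pitch_x * profile_mm.sum())


def layer_volume(tmap: ThicknessMap,
                 geometry: ScanGeometry | None = None) -> float:
    """Volume (mm^3) under a thickness map: cell area x thickness, summed."""
    geo = geometry if geometry is not None else tmap.geometry
    cell_mm2 = geo.pitch_x * geo.pitch_y
    return float(cell_mm2 * (tmap.values / 1000.0).sum())


def enface_attenuation(tmap: ThicknessMap,
                       config: AnalysisConfig | None = None,
                       ) -> tuple[float, float]:
    """(attenuation %, total loss %) of an EZ-RPE thickness map.

    Attenuation counts en face cells thinner than the 20 µm threshold;
    total loss counts cells at zero thickness (up to half an axial sample).
    Both are percentages of all en face cells; loss cells are a subset of
    attenuation cells.
    """
    if config is None:
        config = AnalysisConfig()
    if tmap.layer_pair != "EZ-RPE":
        raise ValueError("attenuation is defined on the EZ-RPE map")
    v = tmap.values
    zero_tol = config.loss_threshold_um + 0.5 * tmap.geometry.axial_scale
    attenuation = 100.0 * float(
        (v < config.attenuation_threshold_um).mean())
    loss = 100.0 * float((v <= zero_tol).mean())
    return attenuation, loss


def compute_eye_metrics(surfaces: BoundarySurfaces, laterality: str = "OD",
                        config: AnalysisConfig | None = None) -> EyeMetrics:
    """The full per-eye metric battery from one set of boundary surfaces.

    Point thicknesses are taken at the fovea and at the juxtafoveal offset
    on the foveal B-scan; areas on the foveal B-scan; volumes over the
    whole cube; attenuation percentages over the whole en face map.
    """
    if config is None:
        config = AnalysisConfig()
    fovea = locate_fovea(surfaces, config)
    off = config.juxtafoveal_offset_mm

    out: dict[str, float] = {"fovea_flagged": fovea.flagged}
    for pair, stem in (("ILM-RPE", "ilm_rpe"), ("ILM-OPL", "ilm_opl"),
                       ("ONLHFL-RPE", "onl_rpe"), ("EZ-RPE", "ez_rpe")):
        tmap = thickness_map(surfaces, pair)
        out[f"{stem}_central_um"] = point_thickness(
            tmap, fovea, 0.0, laterality, config)
        out[f"{stem}_nasal_um"] = point_thickness(
            tmap, fovea, +off, laterality, config)
        out[f"{stem}_temporal_um"] = point_thickness(
            tmap, fovea, -off, laterality, config)

    for pair, stem in (("ONLHFL-EZ", "onl_ez"), ("EZ-RPE", "ez_rpe"),
                       ("ONLHFL-RPE", "onl_rpe")):
        out[f"{stem}_area_mm2"] = bscan_area(surfaces, pair, fovea.y_index)
        out[f"{stem}_volume_mm3"] = layer_volume(thickness_map(surfaces, pair))

    ez_map = thickness_map(surfaces, "EZ-RPE")
    att, loss = enface_attenuation(ez_map, config)
    out["ez_attenuation_pct"] = att
    out["ez_total_loss_pct"] = loss
    return EyeMetrics(**out)
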