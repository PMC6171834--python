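"""Boundary segmentation of macular cubes.

Each B-scan is processed independently. Every boundary is the minimum-cost
left-to-right path through a surface-specific cost image, found by dynamic
programming with a per-column vertical step limit and an optional
smoothness penalty — the standard formulation for ordered retinal
interfaces. Surfaces are extracted sequentially, each restricted to the
band allowed by the surfaces already found:

1. ILM — strongest dark-above/bright-below transition, with a penalty on
   residual brightness above the candidate edge so the vitreoretinal
   interface wins over deeper dark-to-bright edges (the EZ).
2. RPE — top of the brightest axial band below the ILM.
3. EZ — strongest dark-to-bright gradient between ILM and RPE. Columns
   where no EZ edge exceeds a contrast threshold are recorded as EZ = RPE
   (zero EZ-RPE thickness, the "total attenuation" encoding).
4. ONL/HFL — strongest bright-to-dark gradient between ILM and EZ.

Ties in path cost break toward the shallower position. The result always
satisfies ILM <= ONL/HFL <= EZ <= RPE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cube import MacularCube
from .surfaces import (
    PROVENANCE_CORRECTED,
    SURFACE_NAMES,
    BoundarySurfaces,
    OrderingError,
    ordering_violations,
)

__all__ = [
    "SegmentationConfig",
    "SurfaceEdit",
    "QCReport",
    "SignalStrengthError",
    "segment_boundaries",
    "apply_corrections",
    "validate_surfaces",
]


class SignalStrengthError(ValueError):
    """Scan rejected because its signal strength is below the QC minimum."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the boundary segmenter.

    ``step_limit`` bounds the vertical move (axial samples) between
    neighbouring A-scans; ``smoothness_penalty`` adds a per-sample cost to
    vertical moves. ``window`` is the axial extent (samples) of the
    above/below averaging windows used by the ILM and RPE costs.
    ``vitreous_penalty`` weights the brightness above an ILM candidate.
    ``ez_contrast_threshold`` is the minimum dark-to-bright gradient (in
    normalized intensity per sample) for an EZ edge to count as present.
    """

    min_signal_strength: int = 7
    step_limit: int = 2
    smoothness_penalty: float = 0.01
    axial_sigma: float = 1.0
    lateral_sigma: float = 1.0
    window: int = 8
    vitreous_penalty: float = 3.0
    ez_contrast_threshold: float = 0.01
    min_total_um: float = 60.0
    min_inner_um: float = 20.0


@dataclass(frozen=True)
class SurfaceEdit:
    """A manual correction of one surface over a column range of one B-scan."""

    b_scan_index: int
    x_start: int
    x_stop: int  # half-open
    surface_name: str
    new_positions: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.surface_name not in SURFACE_NAMES:
            raise ValueError(f"unknown surface {self.surface_name!r}")
        if len(self.new_positions) != self.x_stop - self.x_start:
            raise ValueError("new_positions length must match the x range")


@dataclass
class QCReport:
    """Validation summary of a set of boundary surfaces."""

    ordering_violations: list[tuple[str, int, int]] = field(default_factory=list)
    out_of_range_cells: int = 0
    corrected_fraction: float = 0.0
    low_confidence_bscans: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.ordering_violations and self.out_of_range_cells == 0


# ---------------------------------------------------------------------------
# dynamic programming

def _min_cost_path(cost: np.ndarray, z_lo: np.ndarray, z_hi: np.ndarray,
                   step: int, penalty: float) -> np.ndarray:
    """Minimum-cost left-to-right path through an (n_x, n_z) cost image.

    The path is confined per column to ``[z_lo[x], z_hi[x]]`` and may move
    at most ``step`` samples between columns, each move sample costing
    ``penalty``. Ties break toward smaller z (argmin takes the first).
    """
    nx, nz = cost.shape
    big = np.inf
    c = cost.copy()
    z = np.arange(nz)
    invalid = (z[None, :] < z_lo[:, None]) | (z[None, :] > z_hi[:, None])
    c[invalid] = big

    shifts = np.arange(-step, step + 1)
    acc = np.empty_like(c)
    acc[0] = c[0]
    # choice[x, z] = shift index taken to arrive at (x, z)
    choice = np.zeros((nx, nz), dtype=np.int8)
    cand = np.empty((len(shifts), nz))
    for x in range(1, nx):
        prev = acc[x - 1]
        for si, s in enumerate(shifts):
            # arriving at z from z - s
            shifted = np.full(nz, big)
            if s >= 0:
                shifted[s:] = prev[:nz - s] if s else prev
            else:
                shifted[:s] = prev[-s:]
            cand[si] = shifted + penalty * abs(s)
        best = np.argmin(cand, axis=0)
        choice[x] = best
        acc[x] = cand[best, np.arange(nz)] + c[x]

    path = np.empty(nx, dtype=int)
    path[-1] = int(np.argmin(acc[-1]))
    for x in range(nx - 1, 0, -1):
        path[x - 1] = path[x] - shifts[choice[x, path[x]]]
    return path


def _snap_to_edge(path: np.ndarray, grad: np.ndarray, radius: int = 3,
                  ) -> np.ndarray:
    """Move each column's position to the strongest gradient within ±radius.

    The DP costs for the ILM and RPE carry regional brightness terms that
    localize the band but bias the path off the edge by a sample; snapping
    to the local gradient extremum removes that bias while the DP keeps the
    global structure.
    """
    nx, nz = grad.shape
    offsets = np.arange(-radius, radius + 1)
    idx = np.clip(path[:, None] + offsets[None, :], 0, nz - 1)
    window = grad[np.arange(nx)[:, None], idx]
    # prefer the deeper of tied extrema: reversed argmax picks the last
    best = window.shape[1] - 1 - np.argmax(window[:, ::-1], axis=1)
    return np.clip(path + offsets[best], 0, nz - 1)


def _preprocess(bscan: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Per-A-scan normalization followed by a small Gaussian smoothing."""
    img = np.asarray(bscan, dtype=float)
    col_mean = img.mean(axis=1, keepdims=True)
    img = img / np.maximum(col_mean, 1e-6)
    return ndimage.gaussian_filter(
        img, sigma=(config.lateral_sigma, config.axial_sigma), mode="nearest")


def _windowed_means(img: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean over [z-w, z) (above) and [z, z+w) (below) per pixel."""
    csum = np.cumsum(np.pad(img, ((0, 0), (w, w)), mode="edge"), axis=1)
    nz = img.shape[1]
    # padded index of z is z + w
    above = (csum[:, w:w + nz] - csum[:, :nz]) / w
    below = (csum[:, 2 * w:2 * w + nz] - csum[:, w:w + nz]) / w
    return above, below


def _segment_bscan(bscan: np.ndarray, config: SegmentationConfig,
                   axial_scale: float) -> tuple[np.ndarray, bool]:
    """Four boundary paths for one B-scan; returns (paths, low_confidence)."""
    img = _preprocess(bscan, config)
    nx, nz = img.shape
    grad = np.gradient(img, axis=1)
    above, below = _windowed_means(img, config.window)
    low_confidence = grad.std() < 1e-6

    full_lo = np.zeros(nx, dtype=int)
    full_hi = np.full(nx, nz - 1, dtype=int)
    step, pen = config.step_limit, config.smoothness_penalty

    # 1. ILM: strongest dark->bright edge with dark vitreous above
    cost_ilm = -grad + config.vitreous_penalty * above
    ilm = _snap_to_edge(_min_cost_path(cost_ilm, full_lo, full_hi, step, pen),
                        grad)

    # 2. RPE: dark->bright edge onto the brightest band below the ILM
    min_total = max(int(round(config.min_total_um / axial_scale)), 1)
    rpe = _min_cost_path(-grad - below,
                         np.minimum(ilm + min_total, nz - 1),
                         full_hi, step, pen)
    rpe = np.maximum(_snap_to_edge(rpe, grad), ilm)

    # 3. EZ: strongest dark->bright gradient between ILM and RPE
    min_inner = max(int(round(config.min_inner_um / axial_scale)), 1)
    ez_lo = np.minimum(ilm + min_inner, rpe)
    ez = _min_cost_path(-grad, ez_lo, np.maximum(rpe - 1, ez_lo), step, pen)
    ez = np.clip(ez, ilm, rpe)
    # absence encoding: no sufficient edge contrast -> EZ sits on the RPE
    weak = grad[np.arange(nx), ez] < config.ez_contrast_threshold
    ez = np.where(weak, rpe, ez)

    # 4. ONL/HFL: strongest bright->dark gradient between ILM and EZ
    onl = _min_cost_path(grad, ilm, np.maximum(ez - 1, ilm), step, pen)
    onl = np.clip(onl, ilm, ez)

    return np.stack([ilm, onl, ez, rpe]).astype(float), low_confidence


def segment_boundaries(cube: MacularCube,
                       config: SegmentationConfig | None = None,
                       ) -> tuple[BoundarySurfaces, QCReport]:
    """Segment the four boundary surfaces of a macular cube.

    Deterministic. Raises :class:`SignalStrengthError` if the cube's signal
    strength is below ``config.min_signal_strength``. B-scans with a
    degenerate (flat) cost image are flagged low-confidence in the QC
    report, not rejected.
    """
    if config is None:
        config = SegmentationConfig()
    if cube.signal_strength < config.min_signal_strength:
        raise SignalStrengthError(
            f"signal strength {cube.signal_strength} below the QC minimum "
            f"{config.min_signal_strength}"
        )
    geometry = cube.geometry
    positions = np.empty((len(SURFACE_NAMES),) + geometry.enface_shape)
    report = QCReport()
    for y in range(geometry.n_bscans_y):
        paths, low_conf = _segment_bscan(cube.bscan(y), config,
                                         geometry.axial_scale)
        positions[:, :, y] = paths
        if low_conf:
            report.low_confidence_bscans.append(y)

    surfaces = BoundarySurfaces(positions, geometry)
    surfaces.validate()
    return surfaces, report


# ---------------------------------------------------------------------------
# manual correction and validation

def apply_corrections(surfaces: BoundarySurfaces,
                      edits: list[SurfaceEdit]) -> BoundarySurfaces:
    """Apply manual surface edits, re-validating the depth ordering.

    Edited cells take the new positions and are flagged ``corrected``; all
    other cells are untouched. An edit that would violate the ordering
    against the untouched surfaces raises :class:`OrderingError` naming the
    surface, B-scan and column, and leaves the input unchanged.
    """
    out = surfaces.copy()
    k_by_name = {name: k for k, name in enumerate(SURFACE_NAMES)}
    nz = surfaces.geometry.n_axial_z
    for edit in edits:
        k = k_by_name[edit.surface_name]
        y = edit.b_scan_index
        if not 0 <= y < surfaces.geometry.n_bscans_y:
            raise IndexError(f"B-scan index {y} out of range")
        if not (0 <= edit.x_start <= edit.x_stop
                <= surfaces.geometry.n_ascans_x):
            raise IndexError("edit x range out of bounds")
        new = np.asarray(edit.new_positions, dtype=float)
        if new.min() < 0 or new.max() > nz - 1:
            raise OrderingError(
                f"edit places {edit.surface_name} outside the axial range")
        sl = slice(edit.x_start, edit.x_stop)
        lower = out.positions[k - 1, sl, y] if k > 0 else None
        upper = out.positions[k + 1, sl, y] if k < 3 else None
        if lower is not None and np.any(new < lower - 1e-9):
            x = edit.x_start + int(np.argmax(new < lower - 1e-9))
            raise OrderingError(
                f"edit places {edit.surface_name} above {SURFACE_NAMES[k-1]} "
                f"at B-scan {y}, column {x}")
        if upper is not None and np.any(new > upper + 1e-9):
            x = edit.x_start + int(np.argmax(new > upper + 1e-9))
            raise OrderingError(
                f"edit places {edit.surface_name} below {SURFACE_NAMES[k+1]} "
                f"at B-scan {y}, column {x}")
        out.positions[k, sl, y] = new
        out.provenance[k, sl, y] = PROVENANCE_CORRECTED
    out.validate()
    return out


def validate_surfaces(surfaces: BoundarySurfaces) -> QCReport:
    """QC report: ordering violations, range violations, corrected fraction."""
    report = QCReport()
    report.ordering_violations = ordering_violations(surfaces)
    nz = surfaces.geometry.n_axial_z
    report.out_of_range_cells = int(
        ((surfaces.positions < 0) | (surfaces.positions > nz - 1)).sum())
    report.corrected_fraction = float(
        (surfaces.provenance == PROVENANCE_CORRECTED).mean())
    return report
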