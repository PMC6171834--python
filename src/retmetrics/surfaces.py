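"""Boundary-surface container shared by the simulator, segmenter and metrics.

Four interfaces are tracked per A-scan, ordered by depth: the internal
limiting membrane (ILM), the proximal boundary of the outer nuclear layer /
Henle fiber layer complex (ONLHFL), the proximal edge of the ellipsoid zone
(EZ), and the proximal edge of the retinal pigment epithelium (RPE).
Positions are in axial samples (fractional allowed), increasing with depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScanGeometry

SURFACE_NAMES: tuple[str, ...] = ("ILM", "ONLHFL", "EZ", "RPE")

PROVENANCE_AUTOMATIC = 0
PROVENANCE_CORRECTED = 1


class OrderingError(ValueError):
    """Raised when the depth ordering ILM <= ONLHFL <= EZ <= RPE is violated."""


@dataclass
class BoundarySurfaces:
    """Axial positions of the four segmented interfaces on the en face grid.

    ``positions`` has shape ``(4, n_ascans_x, n_bscans_y)`` in the order of
    :data:`SURFACE_NAMES`. ``provenance`` marks each en face cell as
    automatically segmented (0) or manually corrected (1).
    """

    positions: np.ndarray
    geometry: ScanGeometry
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        expected = (len(SURFACE_NAMES),) + self.geometry.enface_shape
        if self.positions.shape != expected:
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"geometry-implied shape {expected}"
            )
        if self.provenance is None:
            self.provenance = np.zeros(expected, dtype=np.uint8)
        else:
            self.provenance = np.asarray(self.provenance, dtype=np.uint8)
            if self.provenance.shape != expected:
                raise ValueError("provenance shape does not match positions")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.positions[SURFACE_NAMES.index(name)]

    def copy(self) -> "BoundarySurfaces":
        return BoundarySurfaces(
            self.positions.copy(), self.geometry, self.provenance.copy()
        )

    def validate(self) -> None:
        """Raise :class:`OrderingError` on the first ordering or range violation."""
        viol = ordering_violations(self)
        if viol:
            s, x, y = viol[0]
            raise OrderingError(
                f"surface ordering violated: {s} deeper than next surface at "
                f"A-scan x={x}, B-scan y={y} ({len(viol)} cell(s) total)"
            )
        if self.positions.min() < 0 or self.positions.max() > self.geometry.n_axial_z - 1:
            raise OrderingError(
                "surface positions outside the axial range "
                f"[0, {self.geometry.n_axial_z - 1}]"
            )


def ordering_violations(surfaces: BoundarySurfaces) -> list[tuple[str, int, int]]:
    """All en face cells where a surface lies below its successor.

    Returns ``(surface_name, x_index, y_index)`` triples; the named surface
    is the shallower one of the offending pair.
    """
    out: list[tuple[str, int, int]] = []
    pos = surfaces.positions
    for k in range(len(SURFACE_NAMES) - 1):
        bad = np.argwhere(pos[k] > pos[k + 1] + 1e-9)
        out.extend((SURFACE_NAMES[k], int(x), int(y)) for x, y in bad)
    return out
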