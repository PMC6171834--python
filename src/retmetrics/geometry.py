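"""Scan geometry of a macular cube acquisition.

A macular cube is a raster of A-scans: ``n_ascans_x`` axial profiles per
B-scan, ``n_bscans_y`` B-scans, each A-scan sampled at ``n_axial_z`` depths.
The lateral grid is cell-centered: A-scan *i* of a B-scan sits at
``(i + 0.5) * pitch - extent/2`` millimetres from the cube center, so a
512-wide, 6 mm scan has a pitch of 6/512 mm (1 mm = 85.33 pitches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default axial sampling: 2 mm cube depth over 1024 samples.
DEFAULT_AXIAL_SCALE_UM = 2000.0 / 1024.0


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of a macular cube scan.

    Parameters
    ----------
    n_ascans_x : int
        A-scans per B-scan (fast lateral axis).
    n_bscans_y : int
        Number of B-scans (slow lateral axis).
    n_axial_z : int
        Axial samples per A-scan.
    lateral_extent_x, lateral_extent_y : float
        Scanned extent in millimetres.
    axial_scale : float
        Micrometres per axial sample.
    """

    n_ascans_x: int = 512
    n_bscans_y: int = 128
    n_axial_z: int = 1024
    lateral_extent_x: float = 6.0
    lateral_extent_y: float = 6.0
    axial_scale: float = DEFAULT_AXIAL_SCALE_UM

    def __post_init__(self) -> None:
        for name in ("n_ascans_x", "n_bscans_y", "n_axial_z"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        for name in ("lateral_extent_x", "lateral_extent_y", "axial_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def pitch_x(self) -> float:
        """A-scan pitch along x in mm."""
        return self.lateral_extent_x / self.n_ascans_x

    @property
    def pitch_y(self) -> float:
        """B-scan pitch along y in mm."""
        return self.lateral_extent_y / self.n_bscans_y

    @property
    def enface_shape(self) -> tuple[int, int]:
        return (self.n_ascans_x, self.n_bscans_y)

    @property
    def cube_shape(self) -> tuple[int, int, int]:
        return (self.n_ascans_x, self.n_bscans_y, self.n_axial_z)

    def x_mm(self) -> np.ndarray:
        """Cell-center x coordinates relative to the cube center, in mm."""
        i = np.arange(self.n_ascans_x)
        return (i + 0.5) * self.pitch_x - self.lateral_extent_x / 2.0

    def y_mm(self) -> np.ndarray:
        """Cell-center y coordinates relative to the cube center, in mm."""
        j = np.arange(self.n_bscans_y)
        return (j + 0.5) * self.pitch_y - self.lateral_extent_y / 2.0

    def to_dict(self) -> dict:
        return {
            "n_ascans_x": self.n_ascans_x,
            "n_bscans_y": self.n_bscans_y,
            "n_axial_z": self.n_axial_z,
            "lateral_extent_x": self.lateral_extent_x,
            "lateral_extent_y": self.lateral_extent_y,
            "axial_scale": self.axial_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            n_ascans_x=int(d["n_ascans_x"]),
            n_bscans_y=int(d["n_bscans_y"]),
            n_axial_z=int(d["n_axial_z"]),
            lateral_extent_x=float(d["lateral_extent_x"]),
            lateral_extent_y=float(d["lateral_extent_y"]),
            axial_scale=float(d["axial_scale"]),
        )
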