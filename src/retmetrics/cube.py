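"""The macular cube voxel container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry

LATERALITIES = ("OD", "OS")


@dataclass
class MacularCube:
    """An SD-OCT macular cube volume with acquisition metadata.

    ``intensity`` is indexed ``[x, y, z]`` = (A-scan, B-scan, depth) and is
    non-negative. ``signal_strength`` is the device's 0-10 scan quality
    index; the normative pipeline requires >= 7.
    """

    intensity: np.ndarray
    geometry: ScanGeometry
    laterality: str = "OD"
    signal_strength: int = 10
    subject_id: str = "anonymous"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.intensity.shape != self.geometry.cube_shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"geometry cube shape {self.geometry.cube_shape}"
            )
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        if not 0 <= int(self.signal_strength) <= 10:
            raise ValueError("signal_strength must be in [0, 10]")

    def bscan(self, y: int) -> np.ndarray:
        """One B-scan as an (x, z) image."""
        return self.intensity[:, y, :]
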