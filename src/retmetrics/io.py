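"""Readers and writers for cubes (TIFF + JSON sidecar), surfaces (CSV) and
cohort tables (CSV/XLSX).

The surfaces CSV is the interchange format between pipeline stages: long
format with columns ``x_index, y_index, surface_name, z_position_samples``
(positions kept to 3 decimals) plus a ``provenance`` column. Readers
tolerate and warn about unknown extra columns and preserve unknown sidecar
metadata keys.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cube import MacularCube
from .geometry import ScanGeometry
from .surfaces import SURFACE_NAMES, BoundarySurfaces

logger = logging.getLogger(__name__)

__all__ = [
    "write_cube", "read_cube",
    "write_surfaces", "read_surfaces",
    "write_cohort", "read_cohort",
]

_SIDECAR_REQUIRED = ("geometry", "laterality", "signal_strength")


# ---------------------------------------------------------------------------
# cubes

def write_cube(cube: MacularCube, path, sidecar_path=None, *,
               extra_metadata: dict | None = None) -> tuple[Path, Path]:
    """Write a cube as a multi-page TIFF (one page per B-scan) + sidecar.

    Pages are (z, x) images in B-scan order. The JSON sidecar carries the
    geometry, laterality, signal strength, subject id and any extra
    metadata (preserved verbatim on read).
    """
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    pages = np.transpose(cube.intensity, (1, 2, 0))  # (y, z, x)
    tifffile.imwrite(path, pages.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "geometry": cube.geometry.to_dict(),
        "laterality": cube.laterality,
        "signal_strength": int(cube.signal_strength),
        "subject_id": cube.subject_id,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path, sidecar


def read_cube(path, sidecar_path=None) -> MacularCube:
    """Read a cube written by :func:`write_cube`; round-trips bit-exactly."""
    path = Path(path)
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise ValueError(
            f"sidecar {sidecar} missing required keys: {missing}; "
            f"required: {list(_SIDECAR_REQUIRED)}")
    geometry = ScanGeometry.from_dict(meta["geometry"])
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot parse TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    expected = (geometry.n_bscans_y, geometry.n_axial_z, geometry.n_ascans_x)
    if pages.shape != expected:
        raise ValueError(
            f"TIFF stack shape {pages.shape} does not match the sidecar "
            f"geometry-implied shape {expected}")
    intensity = np.transpose(pages, (2, 0, 1))  # back to (x, y, z)
    cube = MacularCube(intensity, geometry,
                       laterality=meta["laterality"],
                       signal_strength=int(meta["signal_strength"]),
                       subject_id=str(meta.get("subject_id", "unknown")))
    return cube


# ---------------------------------------------------------------------------
# surfaces

def write_surfaces(surfaces: BoundarySurfaces, path) -> Path:
    path = Path(path)
    nx, ny = surfaces.geometry.enface_shape
    xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    frames = []
    for k, name in enumerate(SURFACE_NAMES):
        frames.append(pd.DataFrame({
            "x_index": xi.ravel(), "y_index": yi.ravel(),
            "surface_name": name,
            "z_position_samples": np.round(surfaces.positions[k].ravel(), 3),
            "provenance": surfaces.provenance[k].ravel(),
        }))
    df = pd.concat(frames, ignore_index=True)
    header = "# geometry: " + json.dumps(surfaces.geometry.to_dict()) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    return path


def read_surfaces(path) -> BoundarySurfaces:
    """Read a surfaces CSV; ordering is validated on read."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# geometry:"):
            geometry = ScanGeometry.from_dict(
                json.loads(first.split(":", 1)[1]))
            df = pd.read_csv(fh)
        else:
            raise ValueError(
                f"{path} lacks the '# geometry:' header line")
    required = {"x_index", "y_index", "surface_name", "z_position_samples"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} missing columns {sorted(missing)}")
    extra = set(df.columns) - required - {"provenance"}
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {sorted(extra)}")

    shape = (len(SURFACE_NAMES),) + geometry.enface_shape
    positions = np.full(shape, np.nan)
    provenance = np.zeros(shape, dtype=np.uint8)
    k = df["surface_name"].map(
        {name: i for i, name in enumerate(SURFACE_NAMES)})
    if k.isna().any():
        bad = df.loc[k.isna(), "surface_name"].unique()
        raise ValueError(f"unknown surface name(s) {list(bad)}")
    idx = (k.to_numpy(int), df["x_index"].to_numpy(int),
           df["y_index"].to_numpy(int))
    positions[idx] = df["z_position_samples"].to_numpy(float)
    if "provenance" in df.columns:
        provenance[idx] = df["provenance"].to_numpy(int)
    if np.isnan(positions).any():
        raise ValueError(f"{path} does not cover the full en face grid")
    surfaces = BoundarySurfaces(positions, geometry, provenance)
    surfaces.validate()
    return surfaces


# ---------------------------------------------------------------------------
# cohort tables

_COHORT_REQUIRED = ("subject_id", "age", "sex")


def write_cohort(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table.to_excel(path, index=False)
    else:
        table.to_csv(path, index=False, float_format="%.6g")
    return path


def read_cohort(path, column_map: dict[str, str] | None = None,
                min_signal_strength: int | None = None) -> pd.DataFrame:
    """Read a per-eye cohort table from CSV or XLSX.

    ``column_map`` maps canonical field names to the file's column headers
    (identity for unmapped fields). Rows failing QC — missing age or sex,
    unparseable age, or signal strength below ``min_signal_strength`` when
    that column exists — are dropped with a logged count. Raises if a
    required field resolves to no column, listing the candidates found.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        rename = {src: dst for dst, src in column_map.items()
                  if src in df.columns}
        unmapped = [dst for dst, src in column_map.items()
                    if src not in df.columns]
        if unmapped:
            raise ValueError(
                f"column map entries {unmapped} not found in {path.name}; "
                f"available columns: {list(df.columns)}")
        df = df.rename(columns=rename)
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(
            f"required cohort columns {missing} unresolved; "
            f"available columns: {list(df.columns)}; pass a column_map")

    n0 = len(df)
    df = df.copy()
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    ok = df["age"].notna() & df["age"].between(0, 120) & df["sex"].isin(["M", "F"])
    if min_signal_strength is not None and "signal_strength" in df.columns:
        ss = pd.to_numeric(df["signal_strength"], errors="coerce")
        ok &= ss >= min_signal_strength
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.info("read_cohort(%s): dropped %d row(s) failing QC",
                    path.name, dropped)
    return df[ok].reset_index(drop=True)
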