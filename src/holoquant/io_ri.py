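"""I/O for refractive-index volumes, 2D RI maps and measurement tables.

Volumes are exchanged as multi-page 32-bit float TIFFs, one file per time
point, pages ordered by ascending z; the voxel value is the absolute
refractive index.  Voxel spacing and timing are stored as a JSON sidecar in
the TIFF ImageDescription tag, with a configurable fallback when the metadata
is absent.  Measurement tables are plain CSV with a stable column order.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError

log = logging.getLogger(__name__)

__all__ = [
    "RIVolume",
    "RIMap2D",
    "read_ri_tiff",
    "write_ri_tiff",
    "read_volume_series",
    "write_volume_series",
    "write_measurements",
    "read_measurements",
    "MEASUREMENT_COLUMNS",
]

#: canonical column order of per-object measurement tables
MEASUREMENT_COLUMNS = [
    "frame",
    "id",
    "centroid_y_px",
    "centroid_x_px",
    "area_px",
    "equiv_diameter_px",
    "mean_ri",
    "volume_um3",
    "dry_mass_pg",
]


@dataclass
class RIVolume:
    """A single 3D refractive-index tomogram.

    ``voxels`` is indexed (z, y, x); ``spacing`` is (dz, dy, dx) in
    micrometres.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    frame_index: int = 0
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("RIVolume requires a non-empty 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("RIVolume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RIMap2D:
    """A 2D refractive-index map, usually a maximum-intensity projection."""

    pixels: np.ndarray
    spacing: tuple[float, float]  # (dy, dx) um
    frame_index: int = 0
    time_min: float = 0.0
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("RIMap2D requires a non-empty 2D array")
        self.spacing = tuple(float(s) for s in self.spacing)


def write_ri_tiff(volume: RIVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page float32 TIFF (pages = z ascending)."""
    path = Path(path)
    meta = {
        "spacing_um": list(volume.spacing),
        "frame_index": int(volume.frame_index),
        "time_min": float(volume.time_min),
    }
    tifffile.imwrite(
        path,
        volume.voxels.astype(np.float32, copy=False),
        description=json.dumps(meta),
    )
    return path


def read_ri_tiff(
    path: str | Path,
    fallback_spacing: tuple[float, float, float] = (0.4, 0.18, 0.18),
) -> RIVolume:
    """Read a multi-page float TIFF as an :class:`RIVolume`.

    Raises
    ------
    FormatError
        If the sample format is not floating point — integer pixel types
        cannot carry absolute refractive indices.
    FileNotFoundError
        If ``path`` does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if not np.issubdtype(data.dtype, np.floating):
            raise FormatError(
                f"{path.name}: TIFF sample type {data.dtype} is not float; "
                "refractive-index values require a float export"
            )
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[np.newaxis]
    spacing = fallback_spacing
    frame_index, time_min = 0, 0.0
    if desc:
        try:
            meta = json.loads(desc)
            spacing = tuple(meta.get("spacing_um", spacing))
            frame_index = int(meta.get("frame_index", 0))
            time_min = float(meta.get("time_min", 0.0))
        except (json.JSONDecodeError, TypeError):
            log.warning(
                "%s: no parseable spacing metadata; falling back to %s um",
                path.name,
                fallback_spacing,
            )
    m = re.search(r"frame_(\d+)", path.stem)
    if m:
        frame_index = int(m.group(1))
    return RIVolume(data, spacing, frame_index=frame_index, time_min=time_min)


def write_volume_series(volumes: Iterable[RIVolume], directory: str | Path) -> list[Path]:
    """Write ``frame_####.tiff`` files, one per volume, into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for vol in volumes:
        paths.append(write_ri_tiff(vol, directory / f"frame_{vol.frame_index:04d}.tiff"))
    return paths


def read_volume_series(
    directory: str | Path,
    fallback_spacing: tuple[float, float, float] = (0.4, 0.18, 0.18),
) -> list[RIVolume]:
    """Read all ``frame_####.tiff`` files of a directory, ordered by frame."""
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.tif*"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.tiff files in {directory}")
    return [read_ri_tiff(p, fallback_spacing) for p in paths]


def write_measurements(records: pd.DataFrame | Sequence[dict], path: str | Path) -> Path:
    """Write per-object measurements as CSV with a stable column order.

    An empty record set produces a header-only file.  Floats are written at
    full precision so the table round-trips at better than 1e-9 relative
    tolerance.
    """
    path = Path(path)
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    cols = [c for c in MEASUREMENT_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    if records.empty and not cols:
        cols = MEASUREMENT_COLUMNS
    records = records.reindex(columns=cols)
    records.to_csv(path, index=False, float_format="%.17g")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    return pd.read_csv(path)
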