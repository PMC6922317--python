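"""Fixed-threshold organelle segmentation on projected RI maps.

The pipeline mirrors the classic primary-object detection workflow: a 3D RI
volume is reduced to a 2D map by maximum-intensity projection; pixels at or
above a fixed absolute-RI threshold form the object mask (RI images are
quantitative, so a manual threshold is stable across experiments); connected
components are filtered by their equivalent diameter; and per-object
features are measured on the unmodified RI map.

Presets encode the two organelle classes this was built for: lipid droplets
(threshold 1.354, diameters 1-7 px) and lipid-laden late endosomes
(threshold 1.347, diameters 1-3 px).  Touching objects are not declumped;
they merge into one component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .io_ri import RIMap2D, RIVolume

__all__ = [
    "SegmentationParams",
    "OrganelleRecord",
    "LD_PARAMS",
    "ENDOSOME_PARAMS",
    "MITOCHONDRIA_PARAMS",
    "PRESETS",
    "max_project",
    "segment_objects",
    "measure_frame_series",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Manual-threshold segmentation parameters.

    ``min_diameter_px``/``max_diameter_px`` gate the equivalent diameter
    (diameter of the circle with the component's area), in pixels.
    """

    ri_threshold: float
    min_diameter_px: float = 1.0
    max_diameter_px: float = 7.0
    connectivity: int = 8  # 4 or 8

    def __post_init__(self) -> None:
        if not (0 < self.min_diameter_px <= self.max_diameter_px):
            raise ValueError("need 0 < min_diameter_px <= max_diameter_px")
        if self.ri_threshold <= 1.30:
            raise ValueError("ri_threshold must exceed 1.30 (vacuum/medium floor)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


#: lipid droplets: RI above 1.354, diameters 1-7 px
LD_PARAMS = SegmentationParams(ri_threshold=1.354, min_diameter_px=1, max_diameter_px=7)
#: late endosomes: RI above 1.347, diameters 1-3 px
ENDOSOME_PARAMS = SegmentationParams(ri_threshold=1.347, min_diameter_px=1, max_diameter_px=3)
#: mitochondrial tubules: same RI floor as LDs, wide size window
MITOCHONDRIA_PARAMS = SegmentationParams(ri_threshold=1.354, min_diameter_px=1,
                                         max_diameter_px=40)

PRESETS = {
    "ld": LD_PARAMS,
    "endosome": ENDOSOME_PARAMS,
    "mitochondria": MITOCHONDRIA_PARAMS,
}


@dataclass(frozen=True)
class OrganelleRecord:
    """One detected object in one frame (0-based (y, x) pixel coordinates)."""

    object_id: int
    frame_index: int
    centroid_yx: tuple[float, float]
    area_px: int
    equiv_diameter_px: float
    mean_ri: float

    def as_dict(self) -> dict:
        return {
            "frame": self.frame_index,
            "id": self.object_id,
            "centroid_y_px": self.centroid_yx[0],
            "centroid_x_px": self.centroid_yx[1],
            "area_px": self.area_px,
            "equiv_diameter_px": self.equiv_diameter_px,
            "mean_ri": self.mean_ri,
        }


def max_project(volume: RIVolume) -> RIMap2D:
    """Maximum-intensity projection along z."""
    return RIMap2D(
        pixels=volume.voxels.max(axis=0),
        spacing=volume.spacing[1:],
        frame_index=volume.frame_index,
        time_min=volume.time_min,
        provenance="max_projection",
    )


def segment_objects(
    ri_map: RIMap2D | np.ndarray,
    params: SegmentationParams,
) -> tuple[np.ndarray, list[OrganelleRecord]]:
    """Threshold, connected components, diameter gating, measurement.

    Returns the label image (0 = background, labels renumbered 1..n after
    gating) and the per-object records.  Measurements (mean RI) are taken on
    the unmodified input map.
    """
    pixels = ri_map.pixels if isinstance(ri_map, RIMap2D) else np.asarray(ri_map)
    frame = ri_map.frame_index if isinstance(ri_map, RIMap2D) else 0
    mask = pixels >= params.ri_threshold
    conn = 2 if params.connectivity == 8 else 1
    raw = sk_label(mask, connectivity=conn)
    labels = np.zeros_like(raw)
    records: list[OrganelleRecord] = []
    next_id = 1
    for prop in regionprops(raw, intensity_image=pixels):
        d = prop.equivalent_diameter_area
        if not (params.min_diameter_px <= d <= params.max_diameter_px):
            continue
        labels[raw == prop.label] = next_id
        records.append(OrganelleRecord(
            object_id=next_id,
            frame_index=frame,
            centroid_yx=(float(prop.centroid[0]), float(prop.centroid[1])),
            area_px=int(prop.area),
            equiv_diameter_px=float(d),
            mean_ri=float(prop.intensity_mean),
        ))
        next_id += 1
    return labels, records


def measure_frame_series(
    frames: Sequence[RIMap2D],
    params: SegmentationParams,
) -> pd.DataFrame:
    """Segment a time-ordered sequence of maps into one measurement table."""
    idx = [f.frame_index for f in frames]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError(f"frame indices must be strictly increasing, got {idx}")
    rows = []
    for f in frames:
        _, records = segment_objects(f, params)
        rows.extend(r.as_dict() for r in records)
    cols = ["frame", "id", "centroid_y_px", "centroid_x_px", "area_px",
            "equiv_diameter_px", "mean_ri"]
    return pd.DataFrame(rows, columns=cols)
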