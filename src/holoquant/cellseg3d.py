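"""Whole-cell segmentation on projected RI maps, 3D extension and tracking.

Cells are segmented in three stages, mirroring a primary/secondary-object
workflow:

1. the projected RI map is rescaled so that [1.32, 1.34] maps to [0, 1]
   (intracellular extremes saturate and stop perturbing the cell-scale
   detection);
2. seed blobs (rescaled value >= seed threshold after cell-scale Gaussian
   smoothing) are gated to the expected cell diameter window (80-250 px by
   default) and shrunk to their interior;
3. foreground pixels (smoothed rescaled value >= 0.89 by default) are
   partitioned among seeds by regularised geodesic competition: each pixel
   joins the seed with the cheapest path, where a step costs its Euclidean
   length plus ``regularization`` times the absolute image difference.

The 2D labels are then extended slice-by-slice into 3D: a voxel belongs to
cell c iff it sits under c's 2D footprint and its RI falls inside the RI
range observed for c during the 2D step (expanded by the noise scale).
Tracking across frames uses greedy maximum-IoU matching with a one-parent /
two-children division rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .drymass import CalibrationModel
from .io_ri import RIMap2D, RIVolume

__all__ = [
    "CellSegParams",
    "rescale_ri",
    "detect_seeds",
    "propagate_cells",
    "compute_ri_ranges",
    "extend_mask_3d",
    "cell_measurements",
    "OverlapTracker",
    "track_cells",
    "segment_cells_3d",
]


@dataclass(frozen=True)
class CellSegParams:
    """Parameters of the whole-cell segmentation."""

    rescale_lo: float = 1.32
    rescale_hi: float = 1.34
    secondary_threshold: float = 0.89  # on the rescaled [0, 1] scale
    seed_threshold: float = 0.95
    min_diameter_px: float = 80.0
    max_diameter_px: float = 250.0
    regularization: float = 0.05  # weight of the image term in the step cost
    smooth_sigma_px: float = 2.0
    threshold_orientation: str = "direct"  # or "inverted"
    # expansion of the per-cell RI range, sized to cover the two-sided noise
    # distribution of boundary voxels (~2x the RI noise s.d.)
    ri_range_expand: float = 1e-3

    def __post_init__(self) -> None:
        if not self.rescale_lo < self.rescale_hi:
            raise ValueError("rescale_lo must be < rescale_hi")
        if not (0 < self.secondary_threshold < 1):
            raise ValueError("secondary_threshold must lie in (0, 1)")
        if not (0 < self.min_diameter_px <= self.max_diameter_px):
            raise ValueError("need 0 < min_diameter_px <= max_diameter_px")
        if self.regularization < 0:
            raise ValueError("regularization must be non-negative")
        if self.threshold_orientation not in ("direct", "inverted"):
            raise ValueError("threshold_orientation must be 'direct' or 'inverted'")


def rescale_ri(ri_map: RIMap2D | np.ndarray, lo: float = 1.32, hi: float = 1.34) -> np.ndarray:
    """Clip-rescale RI values: lo -> 0, hi -> 1, clipped outside."""
    pixels = ri_map.pixels if isinstance(ri_map, RIMap2D) else np.asarray(ri_map)
    return np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)


def _smoothed(scaled: np.ndarray, params: CellSegParams) -> np.ndarray:
    if params.smooth_sigma_px > 0:
        return gaussian_filter(scaled, params.smooth_sigma_px)
    return scaled


def _foreground(smoothed: np.ndarray, params: CellSegParams) -> np.ndarray:
    if params.threshold_orientation == "direct":
        return smoothed >= params.secondary_threshold
    return (1.0 - smoothed) >= params.secondary_threshold


def detect_seeds(scaled: np.ndarray, params: CellSegParams) -> np.ndarray:
    """One interior seed component per cell.

    High-valued blobs of the smoothed rescaled map are gated to the
    [min, max] equivalent-diameter window and shrunk to their inner half
    (pixels whose distance to the blob edge is at least half the blob's
    maximum interior distance).  Deterministic; labels follow scan order.
    """
    sm = _smoothed(scaled, params)
    if params.threshold_orientation == "direct":
        blob_mask = sm >= params.seed_threshold
    else:
        blob_mask = (1.0 - sm) >= params.seed_threshold
    raw = sk_label(blob_mask, connectivity=2)
    seeds = np.zeros_like(raw)
    next_id = 1
    for prop in regionprops(raw):
        if not (params.min_diameter_px <= prop.equivalent_diameter_area
                <= params.max_diameter_px):
            continue
        comp = raw == prop.label
        dt = distance_transform_edt(comp)
        interior = dt >= 0.5 * dt.max()
        seeds[interior] = next_id
        next_id += 1
    return seeds


def propagate_cells(
    scaled: np.ndarray, seeds: np.ndarray, params: CellSegParams
) -> np.ndarray:
    """Partition the foreground among seeds by cheapest-path competition.

    Step cost between 8-neighbours = Euclidean step length (1 or sqrt 2, in
    pixels) + ``regularization`` * |image difference|, evaluated on the
    smoothed rescaled map.  Every foreground pixel reachable from a seed is
    assigned to the seed with the minimal accumulated cost (ties break to
    the lowest seed label); unreachable foreground stays 0.
    """
    if seeds.max() == 0:
        raise ValueError("propagation requires at least one seed")
    sm = _smoothed(scaled, params)
    fg = _foreground(sm, params) | (seeds > 0)
    ny, nx = fg.shape
    idx = -np.ones((ny, nx), dtype=np.int64)
    fy, fx = np.nonzero(fg)
    n = len(fy)
    idx[fy, fx] = np.arange(n)

    rows, cols, weights = [], [], []
    shifts = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    for dy, dx, step in shifts:
        ys, xs = fy + dy, fx + dx
        ok = (ys >= 0) & (ys < ny) & (xs >= 0) & (xs < nx)
        ok[ok] &= fg[ys[ok], xs[ok]]
        a = idx[fy[ok], fx[ok]]
        b = idx[ys[ok], xs[ok]]
        w = step + params.regularization * np.abs(
            sm[fy[ok], fx[ok]] - sm[ys[ok], xs[ok]]
        )
        rows.append(a)
        cols.append(b)
        weights.append(w)

    seed_ids = np.unique(seeds[seeds > 0])
    n_seeds = len(seed_ids)
    # virtual source node per seed, 0-cost edges to its member pixels
    for si, sid in enumerate(seed_ids):
        members = idx[(seeds == sid) & fg]
        rows.append(np.full(len(members), n + si))
        cols.append(members)
        weights.append(np.zeros(len(members)))

    g = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n + n_seeds, n + n_seeds),
    ).tocsr()
    dist = dijkstra(g, directed=False, indices=np.arange(n, n + n_seeds))[:, :n]

    labels = np.zeros((ny, nx), dtype=np.int32)
    reachable = np.isfinite(dist).any(axis=0)
    best = np.argmin(dist, axis=0)  # ties -> lowest seed index
    labels[fy[reachable], fx[reachable]] = seed_ids[best[reachable]]
    return labels


def compute_ri_ranges(
    ri_map: RIMap2D | np.ndarray,
    labels: np.ndarray,
    expand: float = 5e-4,
) -> dict[int, tuple[float, float]]:
    """Per-cell [min, max] RI observed under the 2D mask, expanded by the
    noise scale."""
    pixels = ri_map.pixels if isinstance(ri_map, RIMap2D) else np.asarray(ri_map)
    out = {}
    for c in np.unique(labels[labels > 0]):
        vals = pixels[labels == c]
        out[int(c)] = (float(vals.min()) - expand, float(vals.max()) + expand)
    return out


def extend_mask_3d(
    volume: RIVolume,
    labels_2d: np.ndarray,
    ri_ranges: dict[int, tuple[float, float]],
) -> np.ndarray:
    """Slice-wise 3D extension of a 2D cell mask with RI-range gating.

    Voxel (z, y, x) gets label c iff (y, x) lies in cell c's footprint and
    its RI falls inside c's retained range.
    """
    if volume.voxels.shape[1:] != labels_2d.shape:
        raise ValueError(
            f"lateral grid mismatch: volume {volume.voxels.shape[1:]} "
            f"vs labels {labels_2d.shape}"
        )
    out = np.zeros(volume.voxels.shape, dtype=np.int32)
    for c, (lo, hi) in ri_ranges.items():
        foot = labels_2d == c
        if not foot.any():
            continue
        in_range = (volume.voxels >= lo) & (volume.voxels <= hi)
        out[in_range & foot[np.newaxis, :, :]] = c
    return out


def cell_measurements(
    label_volume: np.ndarray,
    volume: RIVolume,
    calib: CalibrationModel,
) -> pd.DataFrame:
    """Per-cell 3D volume, mean dry-mass density and total dry mass.

    Density is (RI - n_m) / alpha per voxel; total mass integrates it over
    the labelled voxels.  Cells with no labelled voxel are flagged with NaN
    measurements.
    """
    labels = np.unique(label_volume[label_volume > 0])
    vv = volume.voxel_volume_um3
    rows = []
    flat = label_volume.ravel()
    dens = (volume.voxels.ravel() - calib.n_medium) / calib.alpha_um3_per_pg
    counts = np.bincount(flat, minlength=int(label_volume.max()) + 1)
    sums = np.bincount(flat, weights=dens, minlength=int(label_volume.max()) + 1)
    for c in labels:
        n = counts[c]
        if n == 0:
            rows.append({"cell_id": int(c), "voxel_count": 0, "volume_um3": np.nan,
                         "mean_density_pg_um3": np.nan, "total_mass_pg": np.nan})
            continue
        rows.append({
            "cell_id": int(c),
            "voxel_count": int(n),
            "volume_um3": n * vv,
            "mean_density_pg_um3": sums[c] / n,
            "total_mass_pg": sums[c] * vv,
        })
    cols = ["cell_id", "voxel_count", "volume_um3", "mean_density_pg_um3",
            "total_mass_pg"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def _iou_table(prev: np.ndarray, cur: np.ndarray) -> dict[tuple[int, int], float]:
    """IoU of every overlapping (prev label, cur label) pair."""
    m = int(cur.max()) + 1
    joint = prev.astype(np.int64) * m + cur.astype(np.int64)
    counts = np.bincount(joint.ravel())
    prev_areas = np.bincount(prev.ravel())
    cur_areas = np.bincount(cur.ravel())
    out = {}
    for key in np.nonzero(counts)[0]:
        p, c = divmod(int(key), m)
        if p == 0 or c == 0:
            continue
        inter = counts[key]
        union = prev_areas[p] + cur_areas[c] - inter
        out[(p, c)] = inter / union
    return out


@dataclass
class OverlapTracker:
    """Greedy maximum-overlap tracker with a division rule.

    Matches with IoU below ``iou_threshold`` start new tracks.  A previous
    object overlapping two or more current objects, each at IoU >=
    ``division_iou``, is treated as a division: both children get new track
    ids with the parent's track recorded as lineage parent.
    """

    iou_threshold: float = 0.3
    division_iou: float = 0.15
    _next_track: int = 1
    _prev_labels: np.ndarray | None = None
    _prev_tracks: dict[int, int] = field(default_factory=dict)

    def update(self, labels: np.ndarray, frame: int) -> pd.DataFrame:
        """Assign track ids to the labels of one frame; returns rows
        (frame, label, track_id, parent_track_id)."""
        cur_ids = [int(c) for c in np.unique(labels[labels > 0])]
        assign: dict[int, tuple[int, int]] = {}
        if self._prev_labels is None:
            for c in cur_ids:
                assign[c] = (self._next_track, 0)
                self._next_track += 1
        else:
            iou = _iou_table(self._prev_labels, labels)
            used_prev: set[int] = set()
            used_cur: set[int] = set()
            # divisions first: one parent, >= 2 children above the division IoU
            for p in sorted(self._prev_tracks):
                children = sorted(
                    c for (pp, c), v in iou.items()
                    if pp == p and v >= self.division_iou and c not in used_cur
                )
                if len(children) >= 2:
                    for c in children:
                        assign[c] = (self._next_track, self._prev_tracks[p])
                        self._next_track += 1
                        used_cur.add(c)
                    used_prev.add(p)
            # greedy one-to-one continuation by descending IoU
            pairs = sorted(iou.items(), key=lambda kv: (-kv[1], kv[0]))
            for (p, c), v in pairs:
                if v < self.iou_threshold:
                    break
                if p in used_prev or c in used_cur or p not in self._prev_tracks:
                    continue
                assign[c] = (self._prev_tracks[p], 0)
                used_prev.add(p)
                used_cur.add(c)
            for c in cur_ids:
                if c not in assign:
                    assign[c] = (self._next_track, 0)
                    self._next_track += 1
        self._prev_labels = labels.copy()
        self._prev_tracks = {c: t for c, (t, _) in assign.items()}
        rows = [{"frame": frame, "label": c, "track_id": t, "parent_track_id": par}
                for c, (t, par) in sorted(assign.items())]
        cols = ["frame", "label", "track_id", "parent_track_id"]
        return pd.DataFrame(rows, columns=cols)


def track_cells(labels_t: np.ndarray, labels_t1: np.ndarray,
                iou_threshold: float = 0.3,
                division_iou: float = 0.15) -> pd.DataFrame:
    """Track a single frame pair; convenience wrapper over OverlapTracker."""
    tr = OverlapTracker(iou_threshold=iou_threshold, division_iou=division_iou)
    tr.update(labels_t, frame=0)
    return tr.update(labels_t1, frame=1)


# ---------------------------------------------------------------------------
# frame-level convenience
# ---------------------------------------------------------------------------


def segment_cells_3d(
    volume: RIVolume,
    params: CellSegParams = CellSegParams(),
) -> tuple[np.ndarray, np.ndarray, dict[int, tuple[float, float]]]:
    """Full single-frame chain: project, rescale, seed, propagate, extend.

    Returns (2D labels, 3D label volume, per-cell RI ranges).  With no
    seeds the labels are empty.
    """
    from .organelles import max_project

    ri_map = max_project(volume)
    scaled = rescale_ri(ri_map, params.rescale_lo, params.rescale_hi)
    seeds = detect_seeds(scaled, params)
    if seeds.max() == 0:
        empty2d = np.zeros(scaled.shape, dtype=np.int32)
        return empty2d, np.zeros(volume.voxels.shape, dtype=np.int32), {}
    labels2d = propagate_cells(scaled, seeds, params)
    ranges = compute_ri_ranges(ri_map, labels2d, expand=params.ri_range_expand)
    labels3d = extend_mask_3d(volume, labels2d, ranges)
    return labels2d, labels3d, ranges
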