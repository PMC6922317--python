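"""Intracellular rotation from feature matching and robust homographies.

Organellar rotation shows up in RI time-lapses as a rigid in-plane motion
of the whole nucleus / nucleoli / lipid-droplet constellation.  Because the
moving texture is rich but unsegmentable as a single object, the motion is
estimated without segmentation: SIFT keypoints are detected on consecutive
2D RI maps, matched by Lowe's ratio test, a homography H mapping frame t
onto frame t+1 is fitted with RANSAC (refined by least squares on the
inliers), and the in-plane rotation angle is extracted from H's linear
block after factoring out uniform scale.

Sign convention: angles are counter-clockwise-positive in image coordinates
(y pointing down); equivalently, clockwise on screen.  Per-interval angles
live in (-180, 180]; the cumulative trace is their running sum over the
intervals that could be estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform

from .errors import (
    EmptyTraceError,
    EstimationError,
    InsufficientFeaturesError,
    ReflectionError,
)
from .io_ri import RIMap2D

__all__ = [
    "MatchSet",
    "HomographyEstimate",
    "RotationTrace",
    "normalize_contrast",
    "match_frames",
    "fit_homography",
    "rotation_angle",
    "rotation_trace",
    "rose_histogram",
]


@dataclass
class MatchSet:
    """Accepted keypoint correspondences between two frames.

    ``src``/``dst`` are (n, 2) arrays of (x, y) pixel positions in frame t
    and t+1 respectively.
    """

    src: np.ndarray
    dst: np.ndarray
    frame_t: int = 0
    frame_t1: int = 1

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=float).reshape(-1, 2)
        self.dst = np.asarray(self.dst, dtype=float).reshape(-1, 2)
        if len(self.src) != len(self.dst):
            raise ValueError("src and dst must pair up")

    @property
    def count(self) -> int:
        return len(self.src)


@dataclass
class HomographyEstimate:
    """A fitted 3x3 homography (normalised so H[2,2] = 1)."""

    H: np.ndarray
    inliers: np.ndarray
    rotation_deg: float

    @property
    def n_inliers(self) -> int:
        return int(np.sum(self.inliers))


def normalize_contrast(img: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Map a float RI map to [0, 1] by a percentile window.

    Gradient-based descriptors need a defined dynamic range; absolute RI
    values (~1.33-1.42) are rescaled by their 1st-99th percentile window.
    """
    lo, hi = np.percentile(img, [p_lo, p_hi])
    if hi <= lo:
        return np.zeros_like(img, dtype=float)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def match_frames(
    img_t: np.ndarray | RIMap2D,
    img_t1: np.ndarray | RIMap2D,
    ratio: float = 0.75,
    min_matches: int = 10,
    frame_t: int = 0,
    frame_t1: int = 1,
) -> MatchSet:
    """SIFT detection + Lowe-ratio descriptor matching between two maps.

    Raises :class:`InsufficientFeaturesError` naming the frame pair when
    fewer than ``min_matches`` correspondences survive the ratio test.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    a = img_t.pixels if isinstance(img_t, RIMap2D) else np.asarray(img_t)
    b = img_t1.pixels if isinstance(img_t1, RIMap2D) else np.asarray(img_t1)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    a = normalize_contrast(a)
    b = normalize_contrast(b)
    det_a, det_b = SIFT(), SIFT()
    try:
        det_a.detect_and_extract(a)
        det_b.detect_and_extract(b)
    except RuntimeError:  # no features found at all
        raise InsufficientFeaturesError(frame_t, frame_t1, 0, min_matches) from None
    if len(det_a.keypoints) == 0 or len(det_b.keypoints) == 0:
        raise InsufficientFeaturesError(frame_t, frame_t1, 0, min_matches)
    pairs = match_descriptors(
        det_a.descriptors, det_b.descriptors, max_ratio=ratio, cross_check=True
    )
    if len(pairs) < min_matches:
        raise InsufficientFeaturesError(frame_t, frame_t1, len(pairs), min_matches)
    # keypoints are (row, col); transforms work in (x, y)
    src = det_a.keypoints[pairs[:, 0]][:, ::-1]
    dst = det_b.keypoints[pairs[:, 1]][:, ::-1]
    return MatchSet(src=src, dst=dst, frame_t=frame_t, frame_t1=frame_t1)


def fit_homography(
    matches: MatchSet,
    reproj_tol_px: float = 3.0,
    seed: int = 0,
    max_trials: int = 1000,
) -> HomographyEstimate:
    """RANSAC homography from matched points, refined on the inliers.

    The consensus model over 4-point samples at the stated reprojection
    tolerance is re-estimated by least squares on its inliers.  The random
    sampling is seeded for reproducibility.
    """
    if matches.count < 4:
        raise EstimationError(f"{matches.count} matches; homography needs >= 4")
    # degenerate geometry: collinear source points leave H unconstrained
    sv = np.linalg.svd(matches.src - matches.src.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise EstimationError("source points are collinear")
    try:
        model, inliers = ransac(
            (matches.src, matches.dst),
            ProjectiveTransform,
            min_samples=4,
            residual_threshold=reproj_tol_px,
            max_trials=max_trials,
            rng=seed,
        )
    except Exception as exc:  # degenerate sample sets
        raise EstimationError(f"RANSAC failed: {exc}") from exc
    if model is None or inliers is None or int(np.sum(inliers)) < 4:
        raise EstimationError("no consensus model with >= 4 inliers")
    if hasattr(ProjectiveTransform, "from_estimate"):
        refined = ProjectiveTransform.from_estimate(
            matches.src[inliers], matches.dst[inliers])
        if not refined:
            raise EstimationError("least-squares refinement on inliers failed")
    else:  # older scikit-image
        refined = ProjectiveTransform()
        if not refined.estimate(matches.src[inliers], matches.dst[inliers]):
            raise EstimationError("least-squares refinement on inliers failed")
    H = refined.params
    if not np.all(np.isfinite(H)) or abs(H[2, 2]) < 1e-12:
        raise EstimationError("degenerate homography")
    H = H / H[2, 2]
    return HomographyEstimate(H=H, inliers=np.asarray(inliers, bool),
                              rotation_deg=rotation_angle(H))


def rotation_angle(H: np.ndarray) -> float:
    """In-plane rotation angle (degrees) of a homography's linear block.

    For rigid in-plane motion H is a similarity; its upper-left 2x2 block
    is s R with uniform scale s = sqrt(det) and the angle follows as
    atan2(H[1,0], H[0,0]) — invariant to s, translation and small
    projective terms.

    Raises :class:`ReflectionError` when the block's determinant is not
    positive (a reflection carries no rotation angle).
    """
    H = np.asarray(H, dtype=float)
    a, b, c, d = H[0, 0], H[0, 1], H[1, 0], H[1, 1]
    det = a * d - b * c
    if det <= 0:
        raise ReflectionError(f"2x2 block determinant {det:.3g} is not positive")
    theta = math.degrees(math.atan2(c, a))
    if theta <= -180.0:
        theta += 360.0
    return theta


@dataclass
class RotationTrace:
    """Per-interval rotation angles of a time-lapse.

    ``angles_deg[k]`` is the rotation from frame k to k+1 (NaN where the
    pair failed); the cumulative trace sums the available intervals.
    """

    angles_deg: np.ndarray
    frame_interval_min: float = 1.0
    failures: dict[int, str] | None = None

    @property
    def cumulative_deg(self) -> np.ndarray:
        return np.nancumsum(self.angles_deg)

    @property
    def total_deg(self) -> float:
        return float(np.nansum(self.angles_deg))

    @property
    def speeds_deg_per_min(self) -> np.ndarray:
        return self.angles_deg / self.frame_interval_min

    @property
    def n_valid(self) -> int:
        return int(np.sum(np.isfinite(self.angles_deg)))

    @property
    def median_speed_deg_per_min(self) -> float:
        return float(np.nanmedian(self.speeds_deg_per_min))


def rotation_trace(
    frames: list[np.ndarray | RIMap2D],
    frame_interval_min: float = 1.0,
    ratio: float = 0.75,
    min_matches: int = 10,
    reproj_tol_px: float = 3.0,
    seed: int = 0,
) -> RotationTrace:
    """Per-adjacent-pair rotation angles across a frame sequence.

    Pairs that fail (too few features, degenerate estimation, reflection)
    are recorded as NaN with the failure reason — never as zero.  If every
    pair fails, :class:`EmptyTraceError` is raised.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    angles = np.full(len(frames) - 1, np.nan)
    failures: dict[int, str] = {}
    for k in range(len(frames) - 1):
        try:
            m = match_frames(frames[k], frames[k + 1], ratio=ratio,
                             min_matches=min_matches, frame_t=k, frame_t1=k + 1)
            est = fit_homography(m, reproj_tol_px=reproj_tol_px, seed=seed)
            angles[k] = est.rotation_deg
        except (InsufficientFeaturesError, EstimationError, ReflectionError) as exc:
            failures[k] = str(exc)
    if not np.any(np.isfinite(angles)):
        raise EmptyTraceError(f"all {len(angles)} frame pairs failed: {failures}")
    return RotationTrace(angles_deg=angles, frame_interval_min=frame_interval_min,
                         failures=failures or None)


def rose_histogram(trace: RotationTrace, bin_deg: float = 20.0):
    """Angular histogram of the per-interval angles.

    ``bin_deg`` must divide 360.  Returns (counts, bin_edges_deg); counts
    sum to the number of valid intervals.
    """
    if bin_deg <= 0 or abs(360.0 / bin_deg - round(360.0 / bin_deg)) > 1e-9:
        raise ValueError(f"bin width {bin_deg} does not divide 360")
    edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)
    valid = trace.angles_deg[np.isfinite(trace.angles_deg)]
    counts, _ = np.histogram(valid, bins=edges)
    return counts, edges


def plot_rotation_trace(trace: RotationTrace, path) -> None:
    """Line plot of per-interval angle and cumulative rotation."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    t = np.arange(len(trace.angles_deg)) * trace.frame_interval_min
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 5), sharex=True)
    ax1.plot(t, trace.angles_deg, ".-")
    ax1.set_ylabel("angle per interval (deg)")
    ax2.plot(t, trace.cumulative_deg, ".-")
    ax2.set_ylabel("cumulative (deg)")
    ax2.set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rose(trace: RotationTrace, path, bin_deg: float = 20.0) -> None:
    """Polar rose plot of per-interval rotation angles."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    counts, edges = rose_histogram(trace, bin_deg)
    centers = np.deg2rad((edges[:-1] + edges[1:]) / 2.0)
    fig = plt.figure(figsize=(4.5, 4.5))
    ax = fig.add_subplot(111, projection="polar")
    ax.bar(centers, counts, width=np.deg2rad(bin_deg), alpha=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
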