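"""Dry-mass calibration and population time-series analytics.

The refractive index of a biological object is linearly related to its
dry-mass concentration through the specific refractive increment alpha:

    rho [pg / um^3] = (n - n_m) / alpha

with n_m the medium RI (default 1.33) and alpha ~ 0.19 mL/g, numerically
equal to 0.19 um^3/pg (the accepted range for protein/lipid mixtures is
0.18-0.20).  A segmented organelle of equivalent diameter d is treated as a
sphere, so its dry mass is rho * (pi/6) d^3.

Per-frame population summaries (count, total and mean mass) and smoothed
per-interval dry-mass fluxes are built on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CalibrationModel",
    "MassSeries",
    "density_from_ri",
    "sphere_volume",
    "object_dry_mass",
    "annotate_dry_mass",
    "mass_series",
    "mass_flux",
    "oa_molecules_per_minute",
]

AVOGADRO = 6.02214076e23
OLEIC_ACID_MOLAR_MASS_G_MOL = 282.46


@dataclass(frozen=True)
class CalibrationModel:
    """Linear RI-to-dry-mass calibration."""

    n_medium: float = 1.33
    alpha_um3_per_pg: float = 0.19  # specific refractive increment, = 0.19 mL/g

    def __post_init__(self) -> None:
        if self.alpha_um3_per_pg <= 0:
            raise ValueError("alpha must be positive")
        if not (1.32 <= self.n_medium <= 1.35):
            raise ValueError(f"n_medium {self.n_medium} outside plausible [1.32, 1.35]")


def density_from_ri(mean_ri: float | np.ndarray, calib: CalibrationModel) -> float | np.ndarray:
    """Dry-mass density rho = (n - n_m) / alpha in pg/um^3.

    Values below the medium RI (possible for noisy near-background
    measurements) are clipped to zero with a warning.
    """
    ri = np.asarray(mean_ri, dtype=float)
    if np.any(ri < calib.n_medium):
        log.warning("mean RI below medium RI; clipping negative density to 0")
    rho = np.clip((ri - calib.n_medium) / calib.alpha_um3_per_pg, 0.0, None)
    return float(rho) if np.isscalar(mean_ri) or rho.ndim == 0 else rho


def sphere_volume(equiv_diameter_px: float | np.ndarray,
                  lateral_spacing_um: float) -> float | np.ndarray:
    """Spherical volume (um^3) from an equivalent diameter in pixels."""
    d = np.asarray(equiv_diameter_px, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    v = np.pi / 6.0 * (d * lateral_spacing_um) ** 3
    return float(v) if v.ndim == 0 else v


def object_dry_mass(record, calib: CalibrationModel, lateral_spacing_um: float) -> float:
    """Dry mass (pg) of one detected organelle under the sphere model."""
    rho = density_from_ri(record.mean_ri, calib)
    return rho * sphere_volume(record.equiv_diameter_px, lateral_spacing_um)


def annotate_dry_mass(
    records: pd.DataFrame, calib: CalibrationModel, lateral_spacing_um: float
) -> pd.DataFrame:
    """Add ``volume_um3`` and ``dry_mass_pg`` columns to a measurement table."""
    out = records.copy()
    if out.empty:
        out["volume_um3"] = pd.Series(dtype=float)
        out["dry_mass_pg"] = pd.Series(dtype=float)
        return out
    vol = sphere_volume(out["equiv_diameter_px"].to_numpy(), lateral_spacing_um)
    rho = density_from_ri(out["mean_ri"].to_numpy(), calib)
    out["volume_um3"] = vol
    out["dry_mass_pg"] = rho * vol
    return out


@dataclass
class MassSeries:
    """Per-frame population summaries of an organelle class.

    ``frames`` columns: frame, time_min, object_count, total_mass_pg,
    mean_mass_per_object_pg (NaN where the count is zero).
    """

    frames: pd.DataFrame
    frame_interval_min: float

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def mass_series(
    records: pd.DataFrame,
    frame_interval_min: float,
    frame_indices: np.ndarray | list[int] | None = None,
) -> MassSeries:
    """Aggregate a per-object table (with ``dry_mass_pg``) into per-frame
    count / total / mean traces.

    ``frame_indices`` lists every acquired frame so that frames with zero
    detected objects appear with count 0; by default the range spanned by
    the records is used.
    """
    if frame_indices is None:
        if records.empty:
            frame_indices = []
        else:
            frame_indices = list(range(int(records["frame"].min()),
                                       int(records["frame"].max()) + 1))
    frame_indices = list(frame_indices)
    grouped = records.groupby("frame")["dry_mass_pg"].agg(["count", "sum"]) \
        if not records.empty else pd.DataFrame(columns=["count", "sum"])
    rows = []
    for f in frame_indices:
        if f in grouped.index:
            n = int(grouped.loc[f, "count"])
            total = float(grouped.loc[f, "sum"])
        else:
            n, total = 0, 0.0
        rows.append({
            "frame": f,
            "time_min": f * frame_interval_min,
            "object_count": n,
            "total_mass_pg": total,
            "mean_mass_per_object_pg": total / n if n > 0 else np.nan,
        })
    return MassSeries(pd.DataFrame(rows), frame_interval_min)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def mass_flux(series: MassSeries, smooth_window_frames: int = 5) -> pd.DataFrame:
    """Per-interval dry-mass fluxes from moving-average-smoothed traces.

    The total and per-object mass traces are smoothed with a centred moving
    average, then differenced between consecutive frames and divided by the
    frame interval.  Returned columns: interval, t_mid_min,
    flux_total_pg_per_min, flux_per_object_pg_per_min.  The cumulative sum
    of flux x interval reconstructs the smoothed trace exactly.
    """
    n = series.n_frames
    if n < 3:
        raise ValueError(f"need at least 3 frames for a flux estimate, got {n}")
    if smooth_window_frames > n:
        raise ValueError(
            f"smoothing window {smooth_window_frames} exceeds series length {n}"
        )
    dt = series.frame_interval_min
    t = series.frames["time_min"].to_numpy()
    total_s = _moving_average(series.frames["total_mass_pg"].to_numpy(float),
                              smooth_window_frames)
    mean_s = _moving_average(series.frames["mean_mass_per_object_pg"].to_numpy(float),
                             smooth_window_frames)
    return pd.DataFrame({
        "interval": np.arange(n - 1),
        "t_mid_min": (t[:-1] + t[1:]) / 2.0,
        "flux_total_pg_per_min": np.diff(total_s) / dt,
        "flux_per_object_pg_per_min": np.diff(mean_s) / dt,
    })


def oa_molecules_per_minute(
    flux_pg_per_min: float,
    molar_mass_g_per_mol: float = OLEIC_ACID_MOLAR_MASS_G_MOL,
) -> float:
    """Convert a dry-mass flux (pg/min) into molecules per minute.

    For oleic acid (282.46 g/mol), 1e-4 pg/min corresponds to ~2.1e5
    molecules/min.
    """
    return flux_pg_per_min * 1e-12 / molar_mass_g_per_mol * AVOGADRO
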