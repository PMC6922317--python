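"""End-to-end scenario runs: simulate (or load), analyze, report.

Each high-level ``analyze_*`` function runs one published pipeline from raw
volumes to its headline statistics; :func:`run_scenario` wraps them with
file output (measurement CSVs, trace plots, a versioned machine-readable
summary).  Frames that fail mid-run are logged and skipped, never silently
zeroed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .cellseg3d import CellSegParams, OverlapTracker, cell_measurements, segment_cells_3d
from .coloc import overlap_fraction, pearson_coloc
from .drymass import CalibrationModel, annotate_dry_mass, mass_flux, mass_series
from .io_ri import write_measurements, write_volume_series
from .organelles import PRESETS, SegmentationParams, max_project, measure_frame_series
from .rotation import plot_rose, plot_rotation_trace, rotation_trace

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

__all__ = [
    "RunConfig",
    "run_scenario",
    "analyze_organelle_timelapse",
    "analyze_mitosis_timelapse",
    "analyze_rotation_timelapse",
    "analyze_static_coloc",
    "zero_crossing_time",
    "flux_crossing_from_mass_trace",
]


# ---------------------------------------------------------------------------
# scenario analytics
# ---------------------------------------------------------------------------


def zero_crossing_time(t: np.ndarray, y: np.ndarray) -> float:
    """Time of the first negative-to-positive crossing, linearly
    interpolated; NaN when there is none."""
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    for k in range(len(y) - 1):
        if y[k] < 0 <= y[k + 1]:
            if y[k + 1] == y[k]:
                return float(t[k + 1])
            return float(t[k] - y[k] * (t[k + 1] - t[k]) / (y[k + 1] - y[k]))
    return float("nan")


def flux_crossing_from_mass_trace(series, fit_window_min: float = 55.0) -> float:
    """Zero-flux time from the early mean-mass trace.

    Over a linear flux ramp the mean per-object mass is quadratic in time,
    so the crossing is estimated as the vertex of a count-weighted quadratic
    fit of the mean-mass trace over the transition window (weights ~ sqrt of
    the object count, since the mean's variance scales as 1/count).  This is
    far more stable at small population sizes than a pointwise sign change
    of the differentiated trace.  Returns NaN when no interior minimum
    exists in the window.
    """
    f = series.frames
    t = f["time_min"].to_numpy(float)
    m = f["mean_mass_per_object_pg"].to_numpy(float)
    n = f["object_count"].to_numpy(float)
    sel = (t <= fit_window_min) & np.isfinite(m) & (n > 0)
    if sel.sum() < 5:
        return float("nan")
    coef = np.polyfit(t[sel], m[sel], 2, w=np.sqrt(n[sel]))
    if coef[0] <= 0:
        return float("nan")
    vertex = -coef[1] / (2.0 * coef[0])
    if not (t[sel].min() < vertex < t[sel].max()):
        return float("nan")
    return float(vertex)


def analyze_organelle_timelapse(
    spec: ph.PhantomSpec,
    params: SegmentationParams | None = None,
    calib: CalibrationModel | None = None,
    smooth_window_frames: int = 5,
    steady_after_min: float | None = None,
):
    """Run the organelle pipeline over a phantom time-lapse.

    Projection -> fixed-threshold segmentation -> dry mass -> population
    series -> fluxes.  Returns (records, series, flux table, summary dict).
    The steady per-object flux is the median per-object flux over intervals
    after ``steady_after_min`` (default: the second half of the run).
    """
    if params is None:
        params = PRESETS[spec.organelles.class_name]
    if calib is None:
        calib = CalibrationModel(n_medium=spec.medium_ri,
                                 alpha_um3_per_pg=spec.alpha_um3_per_pg)
    maps = []
    for vol, _gt in ph.iter_timelapse(spec):
        maps.append(max_project(vol))
    records = measure_frame_series(maps, params)
    records = annotate_dry_mass(records, calib, spec.spacing_um[2])
    series = mass_series(records, spec.frame_interval_min,
                         frame_indices=range(spec.n_frames))
    flux = mass_flux(series, smooth_window_frames)

    counts = series.frames["object_count"].to_numpy()
    fold = float(counts[-1] / counts[0]) if counts[0] > 0 else float("nan")
    if steady_after_min is None:
        steady_after_min = spec.duration_min / 2.0
    late = flux["t_mid_min"] >= steady_after_min
    steady = float(np.nanmedian(flux.loc[late, "flux_per_object_pg_per_min"])) \
        if late.any() else float("nan")
    summary = {
        "count_initial": int(counts[0]),
        "count_final": int(counts[-1]),
        "count_fold_change": fold,
        "steady_flux_per_object_pg_per_min": steady,
        "flux_zero_crossing_min": flux_crossing_from_mass_trace(series),
        "total_mass_final_pg": float(series.frames["total_mass_pg"].iloc[-1]),
    }
    return records, series, flux, summary


def analyze_mitosis_timelapse(
    spec: ph.PhantomSpec,
    params: CellSegParams | None = None,
    calib: CalibrationModel | None = None,
):
    """Run 3D cell segmentation + tracking over a mitosis phantom.

    Returns (per-frame per-cell table with track ids, summary dict).  The
    division frame is the first frame on which a parent splits into two
    lineage-linked children.
    """
    if params is None:
        params = CellSegParams(ri_range_expand=max(2.0 * spec.noise_sd, 1e-4))
    if calib is None:
        calib = CalibrationModel(n_medium=spec.medium_ri,
                                 alpha_um3_per_pg=spec.alpha_um3_per_pg)
    tracker = OverlapTracker()
    rows = []
    failed: list[int] = []
    for vol, _gt in ph.iter_timelapse(spec):
        try:
            labels2d, labels3d, _ranges = segment_cells_3d(vol, params)
            tracks = tracker.update(labels2d, frame=vol.frame_index)
            meas = cell_measurements(labels3d, vol, calib)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("frame %d failed: %s", vol.frame_index, exc)
            failed.append(vol.frame_index)
            continue
        merged = tracks.merge(meas, left_on="label", right_on="cell_id", how="left")
        merged["time_min"] = vol.time_min
        rows.append(merged)
    if not rows:
        raise RuntimeError("cell segmentation failed on every frame")
    cells = pd.concat(rows, ignore_index=True)

    div_rows = cells[cells["parent_track_id"] > 0]
    division_frame = int(div_rows["frame"].min()) if not div_rows.empty else -1
    pre = cells if division_frame < 0 else cells[cells["frame"] < division_frame]
    summary = {
        "division_frame": division_frame,
        "division_time_min": division_frame * spec.frame_interval_min
        if division_frame >= 0 else float("nan"),
        "max_volume_pre_division_um3": float(pre["volume_um3"].max()),
        "min_volume_pre_division_um3": float(
            pre.groupby("frame")["volume_um3"].sum().min()),
        "n_tracks": int(cells["track_id"].nunique()),
        "failed_frames": failed,
    }
    return cells, summary


def analyze_rotation_timelapse(spec: ph.PhantomSpec, seed: int = 0, **kwargs):
    """Run the feature-matching rotation pipeline over a phantom.

    Returns (trace, summary dict with cumulative angle and median speed).
    """
    maps = [max_project(vol) for vol, _ in ph.iter_timelapse(spec)]
    trace = rotation_trace(maps, frame_interval_min=spec.frame_interval_min,
                           seed=seed, **kwargs)
    summary = {
        "n_intervals": len(trace.angles_deg),
        "n_valid_intervals": trace.n_valid,
        "cumulative_angle_deg": trace.total_deg,
        "median_speed_deg_per_min": trace.median_speed_deg_per_min,
    }
    return trace, summary


def analyze_static_coloc(
    spec: ph.PhantomSpec,
    classes: tuple[str, ...] = ("ld", "mitochondria"),
    seed: int = 0,
):
    """Fluorescence/RI cross-validation on one phantom frame.

    Renders a synthetic fluorescence channel per object class, thresholds
    it at half-maximum, segments the RI map with the class presets, and
    reports per-class and combined overlap fractions plus the Pearson
    correlation inside the cell.
    """
    from .organelles import segment_objects

    vol, gt = ph.make_cell_phantom(spec, 0)
    ri_map = max_project(vol)
    shape = ri_map.pixels.shape
    per_class = {}
    fluo_union = np.zeros(shape, bool)
    ri_union = np.zeros(shape, bool)
    fluo_sum = np.zeros(shape, float)
    for i, cls in enumerate(classes):
        img = ph.render_fluorescence(
            gt, cls, shape_yx=shape, spacing_yx_um=spec.spacing_um[1:],
            seed=seed + i,
        )
        fmask = ph.fluorescence_mask(img)
        labels, _ = segment_objects(ri_map, PRESETS[cls])
        res = overlap_fraction(fmask, labels > 0)
        per_class[cls] = res
        fluo_union |= fmask
        ri_union |= labels > 0
        fluo_sum += img
    combined = overlap_fraction(fluo_union, ri_union)
    # Pearson inside the cell footprint (cytoplasm RI floor)
    cell_mask = ri_map.pixels >= (spec.medium_ri + 0.005)
    pearson = pearson_coloc(ri_map.pixels, fluo_sum, cell_mask)
    summary = {
        "overlap_fraction_combined": combined.fraction_a_in_b,
        "overlap_percent_combined": 100.0 * combined.fraction_a_in_b,
        "pearson_in_cell": pearson,
        **{f"overlap_fraction_{c}": per_class[c].fraction_a_in_b for c in classes},
    }
    return per_class, combined, summary


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one end-to-end scenario run."""

    scenario: str
    out_dir: str | Path
    seed: int = 0
    spec: ph.PhantomSpec | None = None  # phantom input ...
    input_dir: str | Path | None = None  # ... or a directory of RI TIFFs
    write_volumes: bool = False
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.spec is not None) and (self.input_dir is not None):
            raise ValueError("set exactly one of spec / input_dir")

    def resolve_spec(self) -> ph.PhantomSpec:
        if self.spec is not None:
            return self.spec
        factories = {
            "static": ph.static_spec,
            "oa_loading": ph.oa_loading_spec,
            "u18666a": ph.u18666a_spec,
            "mitosis": ph.mitosis_spec,
            "rotation": ph.rotation_spec,
        }
        if self.scenario not in factories:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        return factories[self.scenario](seed=self.seed)


def _config_hash(spec: ph.PhantomSpec) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(spec), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_summary(out: Path, scenario: str, seed: int, cfg_hash: str,
                   results: dict) -> Path:
    def clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        return v

    payload = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "scenario": scenario,
        "seed": seed,
        "config_hash": cfg_hash,
        "results": clean(results),
    }
    path = out / "summary.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def run_scenario(config: RunConfig) -> dict:
    """Simulate (or load), analyze and report one scenario end to end.

    Writes measurement CSVs, optional trace plots and ``summary.json`` into
    ``config.out_dir`` and returns the summary payload.  Deterministic for
    a fixed config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.resolve_spec()
    spec = dataclasses.replace(spec, seed=config.seed)
    cfg_hash = _config_hash(spec)
    scenario = config.scenario

    if config.write_volumes:
        write_volume_series((v for v, _ in ph.iter_timelapse(spec)), out / "volumes")

    if scenario in ("oa_loading", "u18666a"):
        records, series, flux, summary = analyze_organelle_timelapse(spec)
        write_measurements(records, out / "objects.csv")
        series.frames.to_csv(out / "mass_series.csv", index=False)
        flux.to_csv(out / "mass_flux.csv", index=False)
        if config.make_plots:
            _plot_mass_traces(series, flux, out / "traces.png")
    elif scenario == "mitosis":
        cells, summary = analyze_mitosis_timelapse(spec)
        cells.to_csv(out / "cells.csv", index=False)
        if config.make_plots:
            _plot_cell_traces(cells, out / "traces.png")
    elif scenario == "rotation":
        trace, summary = analyze_rotation_timelapse(spec, seed=config.seed)
        pd.DataFrame({
            "interval": np.arange(len(trace.angles_deg)),
            "angle_deg": trace.angles_deg,
            "cumulative_deg": trace.cumulative_deg,
        }).to_csv(out / "rotation.csv", index=False)
        if config.make_plots:
            plot_rotation_trace(trace, out / "trace.png")
            plot_rose(trace, out / "rose.png")
    elif scenario == "static":
        _per_class, _combined, summary = analyze_static_coloc(spec, seed=config.seed)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    _write_summary(out, scenario, config.seed, cfg_hash, summary)
    return summary


def _plot_mass_traces(series, flux, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    f = series.frames
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    axes[0, 0].plot(f["time_min"], f["object_count"])
    axes[0, 0].set_ylabel("count")
    axes[0, 1].plot(f["time_min"], f["total_mass_pg"])
    axes[0, 1].set_ylabel("total dry mass (pg)")
    axes[1, 0].plot(f["time_min"], f["mean_mass_per_object_pg"])
    axes[1, 0].set_ylabel("mean mass per object (pg)")
    axes[1, 0].set_xlabel("time (min)")
    axes[1, 1].plot(flux["t_mid_min"], flux["flux_per_object_pg_per_min"])
    axes[1, 1].axhline(0.0, color="k", lw=0.5)
    axes[1, 1].set_ylabel("flux per object (pg/min)")
    axes[1, 1].set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_cell_traces(cells, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 1, figsize=(7, 7), sharex=True)
    for tid, grp in cells.groupby("track_id"):
        axes[0].plot(grp["time_min"], grp["volume_um3"], label=f"track {tid}")
        axes[1].plot(grp["time_min"], grp["mean_density_pg_um3"])
        axes[2].plot(grp["time_min"], grp["total_mass_pg"])
    axes[0].set_ylabel("volume (um^3)")
    axes[0].legend(fontsize=7)
    axes[1].set_ylabel("mean density (pg/um^3)")
    axes[2].set_ylabel("total dry mass (pg)")
    axes[2].set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
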