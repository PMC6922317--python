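import math

import numpy as np
import pytest
from scipy.ndimage import rotate as nd_rotate

from holoquant import phantom as ph
from holoquant.errors import PhantomSpecError


def _voxel_mass(spec, vol):
    vox = vol.voxels.astype(np.float64)
    return (vox - spec.medium_ri).sum() / spec.alpha_um3_per_pg * spec.voxel_volume_um3


class TestRendering:
    def test_empty_scene_voxels_between_medium_and_cytoplasm(self):
        spec = ph.static_spec(
            n_ld=0, n_mitochondria=0, noise_sd=0.0, grid_shape=(12, 64, 64),
            cell=ph.CellGeometry(semi_axes_um=(2.0, 5.0, 5.0),
                                 nucleus_semi_axes_um=None, n_nucleoli=0),
        )
        vol, gt = ph.make_cell_phantom(spec, 0)
        v = vol.voxels
        cyto = spec.cell.cytoplasm_ri
        assert v.min() == pytest.approx(spec.medium_ri, abs=1e-6)
        assert v.max() == pytest.approx(cyto, abs=1e-6)
        # deep inside / far outside are exactly the two levels; only the
        # partial-volume boundary shell lies in between
        center = v[6, 32, 32]
        corner = v[0, 0, 0]
        assert center == pytest.approx(cyto, abs=1e-6)
        assert corner == pytest.approx(spec.medium_ri, abs=1e-6)
        interior_levels = np.isclose(v, cyto, atol=1e-6) | np.isclose(v, spec.medium_ri, atol=1e-6)
        assert interior_levels.mean() > 0.85
        between = ~interior_levels
        assert np.all((v[between] > spec.medium_ri) & (v[between] < cyto))
        assert gt.objects.empty

    def test_mass_bookkeeping_noiseless(self, tiny_static):
        """Voxel-summed dry mass matches analytic ground truth within 1%."""
        spec, vol, gt = tiny_static
        gt_mass = gt.cells["total_dry_mass_pg"].sum()
        assert _voxel_mass(spec, vol) == pytest.approx(gt_mass, rel=0.01)

    def test_mass_bookkeeping_with_tubules(self):
        spec = ph.static_spec(n_ld=6, n_mitochondria=3, seed=5, noise_sd=0.0)
        vol, gt = ph.make_cell_phantom(spec, 0)
        gt_mass = gt.cells["total_dry_mass_pg"].sum()
        assert _voxel_mass(spec, vol) == pytest.approx(gt_mass, rel=0.01)

    def test_object_gt_mass_consistent_with_calibration(self, tiny_static):
        """Per-object ground truth obeys mass = (RI - n_m)/alpha * volume."""
        spec, _vol, gt = tiny_static
        obj = gt.objects
        expect = (obj["ri"] - spec.medium_ri) / spec.alpha_um3_per_pg * obj["volume_um3"]
        np.testing.assert_allclose(obj["dry_mass_pg"], expect, rtol=1e-12)

    def test_determinism_bit_identical(self):
        spec = ph.static_spec(seed=11, grid_shape=(8, 64, 64))
        v1, _ = ph.make_cell_phantom(spec, 0)
        v2, _ = ph.make_cell_phantom(ph.static_spec(seed=11, grid_shape=(8, 64, 64)), 0)
        assert np.array_equal(v1.voxels, v2.voxels)
        v3, _ = ph.make_cell_phantom(ph.static_spec(seed=12, grid_shape=(8, 64, 64)), 0)
        assert not np.array_equal(v1.voxels, v3.voxels)

    def test_ri_bounds_and_containment(self, tiny_static_noisy):
        spec, vol, gt = tiny_static_noisy
        assert vol.voxels.min() >= ph.RI_LO
        assert vol.voxels.max() <= ph.RI_HI
        # organelle centres must lie within the cell body
        cell = next(o for o in gt.scene if o.class_name == "cell")
        cz, cy, cx = cell.center_um
        az, ay, ax = cell.semi_axes_um
        for _, row in gt.objects.iterrows():
            rho2 = (((row.cz_um - cz) / az) ** 2 + ((row.cy_um - cy) / ay) ** 2
                    + ((row.cx_um - cx) / ax) ** 2)
            assert rho2 < 1.0

    def test_organelle_outside_cell_rejected(self):
        spec = ph.static_spec(
            n_ld=0, n_mitochondria=0, noise_sd=0.0, grid_shape=(8, 64, 64),
            cell=ph.CellGeometry(semi_axes_um=(1.2, 3.5, 3.5),
                                 nucleus_semi_axes_um=None, n_nucleoli=0))
        sampler = ph._Sampler(spec)
        bad = ph.Spheroid("ld", (1.6, 0.5, 0.5), (0.4, 0.4, 0.4), 1.39)
        with pytest.raises(PhantomSpecError):
            ph._validate_containment(spec, list(sampler.scene(0)[0]) + [bad])

    def test_frame_outside_schedule_rejected(self):
        spec = ph.static_spec(grid_shape=(8, 64, 64))
        with pytest.raises(PhantomSpecError):
            ph.make_cell_phantom(spec, 1)


class TestScenarios:
    def test_static_limit_of_flat_schedule(self):
        """Flat count and zero growth: all frames identical up to noise."""
        spec = ph.oa_loading_spec(seed=2, duration_min=3.0, grid_shape=(8, 96, 96))
        spec.organelles.count_points = ((0.0, 5.0),)
        spec.organelles.flux_start_pg_min = 0.0
        spec.organelles.flux_steady_pg_min = 0.0
        vols, gt = ph.simulate_timelapse(spec)
        a, b = vols[0].voxels.astype(float), vols[-1].voxels.astype(float)
        assert np.sqrt(np.mean((a - b) ** 2)) < 2.0 * spec.noise_sd
        counts = gt.objects.groupby("frame").size()
        assert set(counts) == {5}

    def test_oa_count_trajectory_endpoints(self):
        spec = ph.oa_loading_spec(seed=0)
        sch = spec.organelles
        assert sch.count_at(0) == 3
        assert sch.count_at(25) == 9
        assert sch.count_at(100) == 48
        assert sch.count_at(180) == 48
        # shared mass trajectory: flux ramp crosses zero at minute 25
        eps = 1e-6
        assert sch.mass_at(25 + eps) - sch.mass_at(25 - eps) == pytest.approx(0, abs=1e-9)
        assert sch.mass_at(24) > sch.mass_at(25) < sch.mass_at(26)

    def test_mitosis_volume_trace_continuous_except_division(self):
        """Per-cell volume is smooth; at the division frame one cell becomes
        two daughters that together carry the parent's volume."""
        spec = ph.mitosis_spec(seed=0)
        sampler = ph._Sampler(spec)
        div = spec.mitosis.division_frame(spec.frame_interval_min)
        per_frame = [sampler.scene(k)[2] for k in range(spec.n_frames)]
        counts = [len(c) for c in per_frame]
        assert counts[:div] == [1] * div
        assert counts[div:] == [2] * (spec.n_frames - div)
        parent = np.array([c["volume_um3"].iloc[0] for c in per_frame[:div]])
        # continuous ramp: no single-step change beyond a tenth of the peak
        assert np.abs(np.diff(parent)).max() < 0.1 * parent.max()
        daughters = per_frame[div]
        assert daughters["volume_um3"].sum() == pytest.approx(
            per_frame[div - 1]["volume_um3"].iloc[0], rel=0.05)
        assert (daughters["parent_id"] == 1).all()

    def test_mitosis_premitotic_and_rounded_volumes(self):
        spec = ph.mitosis_spec(seed=0)
        sampler = ph._Sampler(spec)
        div = spec.mitosis.division_frame(spec.frame_interval_min)
        vols = []
        for k in range(div):
            _, _, cells, _ = sampler.scene(k)
            vols.append(cells["volume_um3"].sum())
        assert max(vols) == pytest.approx(spec.mitosis.v_premitotic_um3, rel=1e-6)
        assert min(vols) == pytest.approx(spec.mitosis.v_rounded_um3, rel=1e-6)

    def test_rotation_ground_truth_angles_sum_exactly(self):
        spec = ph.rotation_spec(speed_deg_per_min=5.0, duration_min=10, seed=1)
        _vols, gt = ph.simulate_timelapse(
            ph.rotation_spec(speed_deg_per_min=5.0, duration_min=2, seed=1,
                             grid_shape=(4, 96, 96)))
        assert np.allclose(gt.rotation["cumulative_deg"],
                           np.cumsum(gt.rotation["angle_deg"]))
        sampler = ph._Sampler(spec)
        assert np.sum(sampler.interval_angles) == pytest.approx(50.0)

    def test_rotation_frame_matches_rotated_first_frame(self):
        """Frame k equals frame 0 rotated by the cumulative angle, up to
        resampling error of the comparison itself."""
        spec = ph.rotation_spec(speed_deg_per_min=15.0, duration_min=2, seed=4,
                                grid_shape=(4, 128, 128), noise_sd=0.0)
        vols, gt = ph.simulate_timelapse(spec)
        proj0 = vols[0].voxels.max(axis=0).astype(float)
        proj2 = vols[2].voxels.max(axis=0).astype(float)
        # rotate frame 0 forward by the cumulative angle about the grid centre
        # (positive angle = counter-clockwise in image coords, i.e. clockwise
        # on screen; nd_rotate rotates counter-clockwise on screen, so negate)
        expect = nd_rotate(proj0, -30.0, reshape=False, order=1, mode="nearest")
        core = (slice(20, -20), slice(20, -20))
        rmse = np.sqrt(np.mean((proj2[core] - expect[core]) ** 2))
        assert rmse < 2e-3  # interpolation error scale, well below contrasts


class TestFluorescence:
    def test_zero_objects_gives_pure_background(self, tiny_static):
        spec, _vol, gt = tiny_static
        img = ph.render_fluorescence(gt, "mitochondria",
                                     shape_yx=(96, 96), seed=0)
        # Poisson background at 10 photons: mean close to 10, no structure
        assert abs(img.mean() - 10.0) < 0.5
        assert img.max() < 30

    def test_point_object_centroid_recovered(self):
        spec = ph.static_spec(n_ld=1, n_mitochondria=0, seed=9, noise_sd=0.0,
                              grid_shape=(8, 64, 64),
                              cell=ph.CellGeometry(semi_axes_um=(1.5, 4.5, 4.5),
                                                   nucleus_semi_axes_um=None,
                                                   n_nucleoli=0))
        _vol, gt = ph.make_cell_phantom(spec, 0)
        img = ph.render_fluorescence(gt, "ld", shape_yx=(64, 64),
                                     peak_photons=5000, seed=1)
        yy, xx = np.mgrid[0:64, 0:64]
        py, px = np.unravel_index(np.argmax(img), img.shape)
        win = (np.abs(yy - py) <= 7) & (np.abs(xx - px) <= 7)
        w = np.where(win, np.clip(img - np.median(img), 0, None), 0.0)
        cy = (w * yy).sum() / w.sum()
        cx = (w * xx).sum() / w.sum()
        row = gt.objects.iloc[0]
        exp_y = row.cy_um / 0.18 - 0.5
        exp_x = row.cx_um / 0.18 - 0.5
        assert math.hypot(cy - exp_y, cx - exp_x) < 0.5

    def test_unknown_class_rejected(self, tiny_static):
        _spec, _vol, gt = tiny_static
        with pytest.raises(ValueError):
            ph.render_fluorescence(gt, "ribosome", shape_yx=(96, 96))

    def test_intensity_nonnegative(self, tiny_static):
        _spec, _vol, gt = tiny_static
        img = ph.render_fluorescence(gt, "ld", shape_yx=(96, 96), seed=2)
        assert img.min() >= 0
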