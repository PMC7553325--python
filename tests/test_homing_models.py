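import math

import numpy as np
import pytest

from beehoming.homing_models import (
    acquire_memory,
    alv_field,
    masked_gradient,
    multi_snapshot_field,
    single_snapshot_field,
)
from beehoming.render import CwNView, PanoramicView
from beehoming.scene import build_scene


class TestAcquireMemory:
    def test_single_nest_snapshot(self, hab_scene):
        mem = acquire_memory(hab_scene, "brightness", 1, 0.0, z_mem=6.0, deg_per_px=2.0)
        assert mem.n == 1
        np.testing.assert_allclose(mem.poses[0][:2], hab_scene.nest)
        assert mem.orientations[0] == 0.0
        assert isinstance(mem.views[0], PanoramicView)

    @pytest.mark.parametrize("n,r", [(4, 15.0), (8, 15.0), (4, 5.0)])
    def test_poses_face_the_nest(self, hab_scene, n, r):
        mem = acquire_memory(hab_scene, "brightness", n, r, z_mem=6.0, deg_per_px=2.0)
        nest = hab_scene.nest
        for k in range(n):
            d = np.linalg.norm(mem.poses[k][:2] - nest)
            assert d == pytest.approx(r, abs=1e-9)
            want = math.degrees(
                math.atan2(nest[1] - mem.poses[k][1], nest[0] - mem.poses[k][0])
            )
            assert mem.orientations[k] == pytest.approx(want, abs=1e-9)
        # consecutive poses are 360/n apart on the circle
        ang = np.degrees(
            np.arctan2(mem.poses[:, 1] - nest[1], mem.poses[:, 0] - nest[0])
        )
        gaps = np.diff(np.unwrap(np.radians(ang)))
        np.testing.assert_allclose(np.degrees(gaps), 360.0 / n, atol=1e-9)

    def test_cwn_kind_converts(self, hab_scene):
        mem = acquire_memory(hab_scene, "cwn", 4, 15.0, z_mem=6.0, deg_per_px=2.0)
        assert all(isinstance(v, CwNView) for v in mem.views)

    def test_invalid_arguments(self, hab_scene):
        with pytest.raises(ValueError):
            acquire_memory(hab_scene, "brightness", 4, 0.0)
        with pytest.raises(ValueError):
            acquire_memory(hab_scene, "brightness", 3, 15.0)
        with pytest.raises(ValueError):
            acquire_memory(hab_scene, "sketch", 1, 0.0)


class TestALV:
    def test_zero_vector_at_nest_in_habituation(self, hab_scene):
        nest = hab_scene.nest
        f = alv_field(
            hab_scene,
            hab_scene,
            x_coords=np.array([nest[0] - 2.0, nest[0], nest[0] + 2.0]),
            y_coords=np.array([nest[1] - 2.0, nest[1], nest[1] + 2.0]),
        )
        assert not f.valid[1, 1]  # undefined exactly at the goal
        np.testing.assert_allclose(f.hv[1, 1], 0.0)

    def test_point_symmetric_landmarks_cancel_at_centre(self):
        # centred nest -> cylinders on a symmetric ring; use stripes at
        # symmetric azimuths so all six bearings cancel at the origin
        from beehoming.scene import ArenaGeometry, CylinderConstellation, StripePattern

        sc = build_scene(
            geometry=ArenaGeometry(nest_radial_distance=0.0),
            cylinders=CylinderConstellation(phase_angles=(0.0, 120.0, 240.0)),
            stripes=StripePattern(centre_azimuths=(0.0, 120.0, -120.0)),
        )
        from beehoming.homing_models import _landmark_bearings

        b = _landmark_bearings(sc, np.zeros((1, 2)))[0]
        np.testing.assert_allclose(b.mean(axis=0), 0.0, atol=1e-12)

    def test_matches_explicit_six_term_average(self, hab_scene):
        from beehoming.homing_models import _landmark_bearings

        p = np.array([[-10.0, 25.0]])
        b = _landmark_bearings(hab_scene, p)[0]
        targets = list(hab_scene.cylinders.centres)
        for az in hab_scene.stripes.azimuths():
            targets.append(
                75.0 * np.array([math.cos(math.radians(az)), math.sin(math.radians(az))])
            )
        want = np.mean(
            [(t - p[0]) / np.linalg.norm(t - p[0]) for t in targets], axis=0
        )
        np.testing.assert_allclose(b.mean(axis=0), want, atol=1e-12)

    def test_unit_vectors_and_convergence(self, hab_scene, hab_grid6):
        f = alv_field(hab_scene, hab_scene, hab_grid6)
        mags = np.linalg.norm(f.hv[f.valid], axis=-1)
        np.testing.assert_allclose(mags, 1.0, atol=1e-12)
        # vectors near the nest point inward (toward the nest)
        nest = hab_scene.nest
        xx, yy = np.meshgrid(f.x_coords, f.y_coords, indexing="ij")
        d = np.hypot(xx - nest[0], yy - nest[1])
        ring = f.valid & (d > 6.0) & (d < 20.0)
        to_nest = np.stack([nest[0] - xx, nest[1] - yy], axis=-1)
        to_nest /= np.linalg.norm(to_nest, axis=-1, keepdims=True)
        cosang = (f.hv * to_nest).sum(axis=-1)[ring]
        assert cosang.mean() > 0.8


class TestMaskedGradient:
    def test_radial_bowl_gradient_points_outward(self):
        coords = np.arange(-5, 6) * 2.0
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        f = xx**2 + yy**2
        valid = np.hypot(xx, yy) <= 10.0
        grad, defined = masked_gradient(f, valid, 2.0)
        inner = np.hypot(xx, yy) <= 6.0
        np.testing.assert_allclose(grad[inner][:, 0], 2 * xx[inner], atol=1e-9)
        np.testing.assert_allclose(grad[inner][:, 1], 2 * yy[inner], atol=1e-9)
        assert defined[inner].all()

    def test_one_sided_at_mask_boundary(self):
        f = np.array([[0.0, 1.0, 4.0]])
        valid = np.array([[True, True, True]])
        grad, _ = masked_gradient(f, valid, 1.0)
        assert grad[0, 0, 1] == 1.0  # forward difference
        assert grad[0, 2, 1] == 3.0  # backward difference
        assert grad[0, 1, 1] == 2.0  # central


class TestSingleSnapshot:
    def test_brightness_landscape_zero_at_memory_position(self, hab_scene, coarse_grid):
        mem = acquire_memory(hab_scene, "brightness", 1, 0.0, z_mem=6.0, deg_per_px=2.0)
        f = single_snapshot_field(coarse_grid, mem)
        assert f.scalar is not None
        assert f.scalar[coarse_grid.valid].min() >= 0.0
        assert f.metadata["model"] == "B1"

    def test_cwn_landscape_peaks_at_one(self, hab_scene):
        # grid point exactly at the memory position: similarity 1 there
        from beehoming.render import build_view_grid
        from beehoming.scene import ArenaGeometry

        sc = build_scene(geometry=ArenaGeometry(nest_radial_distance=0.0))
        grid = build_view_grid(sc, spacing=48.0, altitude=6.0, deg_per_px=2.0)
        mem = acquire_memory(sc, "cwn", 1, 0.0, z_mem=6.0, deg_per_px=2.0)
        f = single_snapshot_field(grid, mem)
        centre = np.argwhere(
            (grid.x_coords[:, None] == 0.0) & (grid.y_coords[None, :] == 0.0)
        )[0]
        assert f.scalar[tuple(centre)] == pytest.approx(1.0, abs=1e-9)

    def test_requires_one_view(self, hab_scene, coarse_grid):
        mem = acquire_memory(hab_scene, "brightness", 4, 15.0, z_mem=6.0, deg_per_px=2.0)
        with pytest.raises(ValueError, match="exactly one"):
            single_snapshot_field(coarse_grid, mem)

    def test_resolution_mismatch(self, hab_scene, coarse_grid):
        mem = acquire_memory(hab_scene, "brightness", 1, 0.0, z_mem=6.0, deg_per_px=1.0)
        with pytest.raises(ValueError, match="resolution"):
            single_snapshot_field(coarse_grid, mem)


class TestMultiSnapshot:
    def test_heading_at_memory_pose_points_at_nest(self, hab_scene, hab_grid6):
        mem = acquire_memory(hab_scene, "brightness", 4, 15.0, z_mem=6.0, deg_per_px=2.0)
        f = multi_snapshot_field(hab_grid6, mem)
        nest = hab_scene.nest
        for k in range(4):
            px, py = mem.poses[k][:2]
            ix = int(round((px - f.x_coords[0]) / f.spacing))
            iy = int(round((py - f.y_coords[0]) / f.spacing))
            gx, gy = f.x_coords[ix], f.y_coords[iy]
            want = math.degrees(math.atan2(nest[1] - gy, nest[0] - gx))
            got = f.headings[ix, iy, k]
            err = abs((got - want + 180.0) % 360.0 - 180.0)
            # within half a pixel of the lattice-snapped nest bearing
            assert err <= 6.0
            assert f.weights[ix, iy, k] == pytest.approx(1.0, abs=1e-9)

    def test_weight_normalization(self, hab_scene, hab_grid6):
        for kind in ("brightness", "cwn"):
            mem = acquire_memory(hab_scene, kind, 4, 15.0, z_mem=6.0, deg_per_px=2.0)
            f = multi_snapshot_field(hab_grid6, mem)
            wmax = f.weights[hab_grid6.valid].max(axis=-1)
            np.testing.assert_allclose(wmax, 1.0, atol=1e-12)
            assert f.weights[hab_grid6.valid].min() >= 0.0

    def test_hv_equals_complex_sum_of_headings(self, hab_scene, coarse_grid):
        mem = acquire_memory(hab_scene, "cwn", 4, 15.0, z_mem=6.0, deg_per_px=2.0)
        f = multi_snapshot_field(coarse_grid, mem)
        for ix, iy in np.argwhere(coarse_grid.valid & f.valid):
            z = (f.weights[ix, iy] * np.exp(1j * np.radians(f.headings[ix, iy]))).sum()
            want = np.array([z.real, z.imag]) / abs(z)
            np.testing.assert_allclose(f.hv[ix, iy], want, atol=1e-9)

    def test_requires_multiple_views(self, hab_scene, coarse_grid):
        mem = acquire_memory(hab_scene, "brightness", 1, 0.0, z_mem=6.0, deg_per_px=2.0)
        with pytest.raises(ValueError, match="at least 2"):
            multi_snapshot_field(coarse_grid, mem)


class TestCircularMeanFusion:
    """Direct checks of the weighted circular mean on constructed inputs."""

    @pytest.mark.parametrize("theta", [0.0, 45.0, -120.0])
    def test_equal_headings_survive(self, theta):
        w = np.array([0.3, 1.0, 0.7])
        z = (w * np.exp(1j * np.radians(np.full(3, theta)))).sum()
        assert math.degrees(np.angle(z)) == pytest.approx(theta, abs=1e-9)

    def test_symmetric_pair_averages_to_zero(self):
        z = np.exp(1j * np.radians(40.0)) + np.exp(1j * np.radians(-40.0))
        assert np.angle(z) == pytest.approx(0.0, abs=1e-12)
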