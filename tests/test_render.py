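import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from beehoming.render import (
    PoseError,
    build_view_grid,
    contrast_weighted_nearness,
    michelson_contrast,
    render_panorama,
    rotate_view,
)
from beehoming.scene import build_scene


class TestRenderPanorama:
    def test_centre_view_wall_distance(self):
        sc = build_scene(condition="0/0")
        view, near = render_panorama(sc, (0.0, 0.0, 45.0), 0.0, deg_per_px=2.0)
        # at half arena height the near-equator row (elevation 1 deg) sees
        # only the wall: 75 / cos(1 deg) for every azimuth
        eq = near.distance[near.distance.shape[0] // 2]
        np.testing.assert_allclose(eq, 75.0 / np.cos(np.radians(1.0)), atol=1e-6)
        # off-stripe wall pixels are bright
        row = view.brightness[near.distance.shape[0] // 2]
        assert set(np.round(np.unique(row), 6)) <= {0.0, 1.0}

    def test_cylinder_silhouette_half_width(self):
        sc = build_scene(condition="0/0")
        # view the cylinder at (30, -10) from 20 cm due south: its angular
        # half width at eye height is asin(r/d); other cues are > 30 cm away
        c = sc.cylinders.centres[2]
        d = 20.0
        eye = np.array([c[0], c[1] - d, 6.0])
        view, near = render_panorama(sc, eye, 90.0, deg_per_px=1.0)
        row = near.distance[90]  # equator row
        width_deg = float((row < 25.0).sum())
        expected = 2.0 * math.degrees(math.asin(1.0 / d))
        assert width_deg == pytest.approx(expected, abs=2.0)  # 1 px per edge

    def test_occlusion_of_third_stripe_at_nest(self):
        sc = build_scene(condition="0/0")
        nest = sc.nest
        for z, expect_visible in ((6.0, False), (15.0, True)):
            view, near = render_panorama(sc, (nest[0], nest[1], z), 0.0, 1.0)
            az = -180.0 + (np.arange(view.n_u) + 0.5)
            sel = (az > 130) & (az < 165)  # direction of the third stripe
            stripe_px = (view.brightness[:, sel] < 0.5) & (near.distance[:, sel] > 30)
            assert stripe_px.any() == expect_visible

    def test_pose_errors(self):
        sc = build_scene(condition="0/0")
        with pytest.raises(PoseError):
            render_panorama(sc, (80.0, 0.0, 6.0))
        with pytest.raises(PoseError):
            render_panorama(sc, (0.0, 0.0, 95.0))
        c = sc.cylinders.centres[0]
        with pytest.raises(PoseError):
            render_panorama(sc, (c[0], c[1], 6.0))

    def test_distance_continuity_along_equator(self):
        sc = build_scene(condition="0/0")
        _, near = render_panorama(sc, (20.0, -10.0, 6.0), 0.0, 2.0)
        row = near.distance[near.distance.shape[0] // 2]
        jumps = np.abs(np.diff(np.concatenate([row, row[:1]])))
        # jumps above 5 cm only at object silhouettes (finite count)
        assert (jumps > 5.0).sum() < 20

    def test_render_equivariance_under_rotation(self):
        base = build_scene(condition="0/0")
        rotated = build_scene(condition="90/90")
        p = np.array([10.0, -30.0, 6.0])
        rp = np.array([30.0, 10.0, 6.0])  # p rotated by +90
        v1, n1 = render_panorama(base, p, 0.0, 2.0)
        v2, n2 = render_panorama(rotated, rp, 90.0, 2.0)
        same = np.isclose(v1.brightness, v2.brightness)
        assert same.mean() > 0.998  # pixel quantization may flip edge pixels
        assert np.isclose(n1.distance, n2.distance, rtol=1e-3).mean() > 0.998


class TestMichelsonContrast:
    def test_uniform_is_zero(self):
        assert michelson_contrast(np.full((8, 16), 0.7)).max() == 0.0

    def test_checkerboard_is_one(self):
        img = np.indices((6, 12)).sum(axis=0) % 2
        assert np.all(michelson_contrast(img.astype(float)) == 1.0)

    @given(
        arrays(
            float,
            (8, 6),
            elements=st.floats(0, 1, allow_nan=False, width=32),
        )
    )
    def test_matches_per_pixel_loop_oracle(self, img):
        got = michelson_contrast(img)
        n_v, n_u = img.shape
        for v in range(n_v):
            for u in range(n_u):
                lo = max(v - 1, 0)
                hi = min(v + 2, n_v)
                cols = [(u + du) % n_u for du in (-1, 0, 1)]
                win = img[lo:hi][:, cols]
                mx, mn = win.max(), win.min()
                want = (mx - mn) / (mx + mn) if mx + mn > 0 else 0.0
                assert got[v, u] == pytest.approx(want, abs=1e-12)


class TestCwN:
    def test_uniform_brightness_gives_zero(self):
        sc = build_scene(condition="0/0")
        view, near = render_panorama(sc, (0.0, 0.0, 45.0), 0.0, 2.0)
        view = type(view)(np.full_like(view.brightness, 0.5), view.position, 0.0, 2.0)
        cwn = contrast_weighted_nearness(view, near)
        assert cwn.values.max() == 0.0

    def test_nonzero_only_at_edges(self):
        sc = build_scene(condition="0/0")
        nest = sc.nest
        view, near = render_panorama(sc, (nest[0], nest[1], 6.0), 0.0, 1.0)
        cwn = contrast_weighted_nearness(view, near)
        contrast = michelson_contrast(view.brightness)
        assert np.all((cwn.values > 0) == (contrast > 0))
        assert cwn.values.min() >= 0.0
        assert np.all(np.isfinite(cwn.values))

    def test_edge_cwn_halves_with_doubled_distance(self):
        # the same cylinder seen from 10 cm vs 20 cm: edge nearness halves
        # while edge contrast stays saturated
        sc = build_scene(condition="0/0")
        c = sc.cylinders.centres[2]  # (30, -10), no other cue within 30 cm
        out = []
        for d in (10.0, 20.0):
            view, near = render_panorama(sc, (c[0], c[1] - d, 6.0), 90.0, 1.0)
            cwn = contrast_weighted_nearness(view, near)
            window = cwn.values[:, 165:195]  # +/- 15 deg about the target
            out.append(window[window > 0].max())
        assert out[0] / out[1] == pytest.approx(2.0, rel=0.15)

    def test_shape_mismatch_raises(self):
        sc = build_scene(condition="0/0")
        view, near = render_panorama(sc, (0.0, 0.0, 6.0), 0.0, 2.0)
        view2, _ = render_panorama(sc, (0.0, 0.0, 6.0), 0.0, 1.0)
        with pytest.raises(ValueError, match="shape"):
            contrast_weighted_nearness(view2, near)


class TestRotateView:
    @given(st.integers(-720, 720))
    def test_rotation_inverts(self, deg):
        rng = np.random.default_rng(0)
        img = rng.random((6, 24))
        res = 360.0 / 24
        got = rotate_view(rotate_view(img, deg * res, res), -deg * res, res)
        np.testing.assert_array_equal(got, img)

    def test_full_turn_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((4, 12))
        np.testing.assert_array_equal(rotate_view(img, 360.0, 30.0), img)

    def test_rotation_matches_rerender(self):
        sc = build_scene(condition="0/0")
        p = (25.0, 5.0, 6.0)
        v0, _ = render_panorama(sc, p, 0.0, 2.0)
        v90, _ = render_panorama(sc, p, 90.0, 2.0)
        np.testing.assert_array_equal(
            rotate_view(v0.brightness, 90.0, 2.0), v90.brightness
        )

    def test_non_multiple_shift_raises(self):
        with pytest.raises(ValueError, match="multiple"):
            rotate_view(np.zeros((4, 8)), 10.0, 45.0 / 2)


class TestViewGrid:
    def test_point_count_matches_lattice_enumeration(self, hab_grid6):
        sc = hab_grid6.scene
        coords = hab_grid6.x_coords
        count = 0
        for x in coords:
            for y in coords:
                if math.hypot(x, y) > sc.geometry.radius - 1.0:
                    continue
                if any(
                    math.hypot(x - cx, y - cy) <= sc.cylinders.cylinder_radius
                    for cx, cy in sc.cylinders.centres
                ):
                    continue
                count += 1
        assert int(hab_grid6.valid.sum()) == count

    def test_views_oriented_along_x(self, hab_grid6):
        ix, iy = map(int, np.argwhere(hab_grid6.valid)[0])
        view, _ = hab_grid6.view_at(ix, iy)
        assert view.orientation == 0.0

    def test_single_point_grid(self):
        sc = build_scene(condition="0/0")
        grid = build_view_grid(sc, spacing=80.0, altitude=6.0, deg_per_px=2.0)
        assert grid.valid.sum() == 1

    def test_save_creates_index(self, tmp_path):
        sc = build_scene(condition="0/0")
        grid = build_view_grid(sc, spacing=80.0, altitude=6.0, deg_per_px=2.0)
        grid.save(tmp_path / "grid")
        assert (tmp_path / "grid" / "grid.npz").exists()
        assert (tmp_path / "grid" / "index.json").exists()
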