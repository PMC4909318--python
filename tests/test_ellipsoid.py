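"""Ellipse fitting, circularity, and 3D ellipsoid extrapolation."""

import numpy as np
import pytest

from spheroid25d import (
    Ellipsoid3D,
    circularity,
    compute_projection,
    ellipsoid_cap_volume,
    ellipsoid_volume,
    extrapolate_ellipsoid,
    filter_by_circularity,
    fit_ellipse,
    segment_spheroids,
)
from spheroid25d.segmentation import SpheroidMask2D

from conftest import make_sphere_scene, render_ellipse_mask


def as_spheroid(mask, label=1, pixel_size=1.0):
    return SpheroidMask2D(
        label=label,
        mask=mask,
        mean_mip_intensity=1.0,
        area_um2=float(mask.sum()) * pixel_size**2,
    )


class TestFitEllipse:
    def test_disk_self_recovery(self):
        mask = render_ellipse_mask(20, 20, 0.0)
        ell, err = fit_ellipse(mask)
        assert ell.a == pytest.approx(20, abs=0.5)
        assert ell.b == pytest.approx(20, abs=0.5)
        assert err < 0.05

    def test_rotated_ellipse_recovery(self):
        theta = np.deg2rad(30)
        mask = render_ellipse_mask(30, 15, theta)
        ell, _ = fit_ellipse(mask)
        assert ell.a == pytest.approx(30, rel=0.05)
        assert ell.b == pytest.approx(15, rel=0.05)
        dtheta = abs(ell.orientation - theta)
        assert min(dtheta, np.pi - dtheta) < np.deg2rad(3)

    def test_l_shape_fits_worse_than_disk(self):
        l_mask = np.zeros((60, 60), bool)
        l_mask[10:50, 10:22] = True
        l_mask[38:50, 10:50] = True
        disk = render_ellipse_mask(np.sqrt(l_mask.sum() / np.pi),
                                   np.sqrt(l_mask.sum() / np.pi), 0.0, (60, 60))
        _, err_l = fit_ellipse(l_mask)
        _, err_d = fit_ellipse(disk)
        assert err_l > 3 * err_d

    def test_micrometre_scaling(self):
        mask = render_ellipse_mask(20, 10, 0.0)
        ell, _ = fit_ellipse(mask, pixel_size_xy=1.3)
        assert ell.a == pytest.approx(26, rel=0.05)

    def test_degenerate_mask_raises(self):
        line = np.zeros((20, 20), bool)
        line[10, 2:18] = True
        with pytest.raises(ValueError):
            fit_ellipse(line)
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((5, 5), bool))

    def test_render_fit_render_round_trip(self):
        """Symmetric difference below 10% of area for a >= 5 px ellipses."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.uniform(5, 40)
            b = a / rng.uniform(1.0, 3.0)
            th = rng.uniform(0, np.pi)
            mask = render_ellipse_mask(a, b, th)
            ell, _ = fit_ellipse(mask)
            refit = render_ellipse_mask(
                ell.a, ell.b, ell.orientation, mask.shape,
                (ell.center_x, ell.center_y),
            )
            assert (mask ^ refit).sum() / mask.sum() < 0.10


class TestCircularity:
    def test_disk_is_nearly_one(self):
        assert circularity(render_ellipse_mask(20, 20, 0.0)) >= 0.95

    def test_ellipse_equals_axis_ratio(self):
        for ratio in (1.5, 2.0, 3.0):
            mask = render_ellipse_mask(30, 30 / ratio, 0.3)
            assert circularity(mask) == pytest.approx(1 / ratio, abs=0.05)

    def test_dumbbell_below_single_disk(self):
        disk = render_ellipse_mask(15, 15, 0.0, (40, 80), (20, 20))
        dumbbell = disk | render_ellipse_mask(15, 15, 0.0, (40, 80), (42, 20))
        assert circularity(dumbbell) < circularity(disk)

    def test_monotone_decreasing_in_aspect_ratio(self):
        vals = [
            circularity(render_ellipse_mask(30, 30 / r, 0.0))
            for r in (1.0, 1.5, 2.0, 2.5, 3.0)
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))


class TestCircularityFilter:
    def test_threshold_extremes(self):
        masks = [as_spheroid(render_ellipse_mask(20, 10, 0.0), label=1)]
        kept, rejected = filter_by_circularity(masks, 0.0)
        assert len(kept) == 1 and kept[0].roundness_class == "elliptical"
        masks[0].circularity = None
        kept, rejected = filter_by_circularity(masks, 1.0)
        assert len(rejected) == 1
        assert rejected[0].roundness_class == "non-elliptical"

    def test_overlapping_pair_rejected_separated_kept(self):
        """Two laterally overlapping spheroids merge into one low-circularity
        mask; well-separated ones survive the same threshold."""
        from spheroid25d.synthetic import SceneSpec, generate_scene

        spec = SceneSpec(volume_shape=(16, 256, 256), seed=8, mu=0.0)
        ells = [
            Ellipsoid3D(60.0, 60.0, 80.0, 35, 35, 35),
            Ellipsoid3D(110.0, 60.0, 80.0, 35, 35, 35),  # overlaps the first
            Ellipsoid3D(240.0, 80.0, 80.0, 30, 30, 30),
            Ellipsoid3D(90.0, 240.0, 80.0, 30, 30, 30),
            Ellipsoid3D(240.0, 240.0, 30.0, 30, 30, 30),
        ]
        scene = generate_scene(spec, ellipsoids=ells)
        proj = compute_projection(scene.stable)
        seg = segment_spheroids(proj)
        kept, rejected = filter_by_circularity(seg.spheroids, 0.7)
        assert len(rejected) >= 1
        merged = max(seg.spheroids, key=lambda s: s.area_px)
        assert merged in rejected  # the merged double mask goes


class TestExtrapolate:
    def test_sphere_round_trip(self):
        scene, truth = make_sphere_scene(40.0, 80.0, seed=3, mu=0.0)
        proj = compute_projection(scene.stable)
        seg = segment_spheroids(proj)
        s = max(seg.spheroids, key=lambda q: q.area_px)
        ell, _ = fit_ellipse(s, proj.pixel_size_xy)
        eo, profile = extrapolate_ellipsoid(ell, s, proj, scene.stable)
        # one z-step of tolerance on the axial semi-axis and the centre depth
        assert abs(eo.c - 40.0) <= 10.0
        assert abs(eo.center_z - 80.0) <= 10.0
        assert profile.z_top == pytest.approx(eo.center_z - eo.c)

    def test_small_mask_uses_in_plane_radius(self):
        scene, truth = make_sphere_scene(15.0, 80.0, seed=4, mu=0.0)
        proj = compute_projection(scene.stable)
        seg = segment_spheroids(proj)
        s = max(seg.spheroids, key=lambda q: q.area_px)
        ell, _ = fit_ellipse(s, proj.pixel_size_xy)
        # equivalent radius ~15 um < default min_radius 24 um
        eo, _ = extrapolate_ellipsoid(ell, s, proj, scene.stable, min_radius=24.0)
        assert eo.c == pytest.approx((ell.a + ell.b) / 2.0)

    def test_oblate_ellipsoid_recovery(self):
        from spheroid25d.synthetic import SceneSpec, generate_scene

        spec = SceneSpec(volume_shape=(20, 128, 128), seed=6, mu=0.0, n_spheroids=1)
        truth = Ellipsoid3D(83.2, 83.2, 100.0, 50, 50, 25)
        scene = generate_scene(spec, ellipsoids=[truth])
        proj = compute_projection(scene.stable)
        seg = segment_spheroids(proj)
        s = max(seg.spheroids, key=lambda q: q.area_px)
        ell, _ = fit_ellipse(s, proj.pixel_size_xy)
        eo, _ = extrapolate_ellipsoid(ell, s, proj, scene.stable)
        assert abs(eo.c - 25.0) <= max(0.2 * 25.0, 10.0)


class TestVolumes:
    def test_sphere_and_closed_form(self):
        assert ellipsoid_volume(Ellipsoid3D(0, 0, 0, 7, 7, 7)) == pytest.approx(
            4 / 3 * np.pi * 343
        )
        assert ellipsoid_volume(Ellipsoid3D(0, 0, 0, 10, 20, 30)) == pytest.approx(
            25132.74, abs=0.01
        )

    def test_symmetry_in_lateral_axes(self):
        assert ellipsoid_volume(Ellipsoid3D(0, 0, 0, 10, 20, 5)) == pytest.approx(
            ellipsoid_volume(Ellipsoid3D(0, 0, 0, 20, 10, 5))
        )

    def test_invalid_axes_raise(self):
        with pytest.raises(ValueError):
            Ellipsoid3D(0, 0, 0, 1, 1, 0)
        with pytest.raises(ValueError):
            ellipsoid_cap_volume(1, 1, 0, 1)

    def test_cap_volume_special_cases(self):
        a, b, c = 13.0, 9.0, 21.0
        full = 4 / 3 * np.pi * a * b * c
        assert ellipsoid_cap_volume(a, b, c, 2 * c) == pytest.approx(full)
        assert ellipsoid_cap_volume(a, b, c, c) == pytest.approx(full / 2)

    def test_cap_volume_matches_numeric_integration(self):
        a, b, c = 10.0, 15.0, 20.0
        for h in (5.0, 12.0, 33.0):
            zs = np.linspace(-c, -c + min(h, 2 * c), 20001)
            areas = np.pi * a * b * (1 - (zs / c) ** 2).clip(0)
            assert ellipsoid_cap_volume(a, b, c, h) == pytest.approx(
                np.trapezoid(areas, zs), rel=1e-5
            )
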