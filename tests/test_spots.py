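"""LoG scale selection, spot detection, and corrected counting."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from spheroid25d import (
    Ellipsoid3D,
    ImageStack,
    Visibility,
    assign_and_count,
    detect_spots,
    ellipsoid_cap_volume,
    ellipsoid_volume,
    median_mask_intensity,
    merge_close_spots,
    optimal_log_scale,
)
from spheroid25d.spots import SpheroidContext, Spot, SpotParams


def blob_image(s, centers, shape=(220, 220), amplitude=100.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for cy, cx in centers:
        img += amplitude * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s * s)))
    return img


def spaced_centers(rng, n, lo, hi, dmin):
    centers = []
    while len(centers) < n:
        c = rng.uniform(lo, hi, 2)
        if centers and np.min(np.linalg.norm(np.array(centers) - c, axis=1)) < dmin:
            continue
        centers.append(c)
    return centers


class TestOptimalScale:
    def test_gaussian_blobs_recover_their_scale(self):
        rng = np.random.default_rng(2)
        grid_step = (10.0) ** (1 / 19)  # 20 log-spaced sigmas over one decade
        for s in (2.0, 4.0, 6.0):
            img = blob_image(s, spaced_centers(rng, 12, 25, 195, 35))
            sigma = optimal_log_scale(img, 8.0, 1.0)
            assert s / grid_step <= sigma <= s * grid_step * 1.001

    def test_disks_recover_r_over_sqrt2(self):
        rng = np.random.default_rng(4)
        grid_step = (10.0) ** (1 / 19)
        for r in (4.0, 7.0):
            img = np.zeros((220, 220))
            for cy, cx in spaced_centers(rng, 12, 25, 195, 35):
                rr, cc = draw_disk((cy, cx), r, shape=img.shape)
                img[rr, cc] = 100.0
            sigma = optimal_log_scale(img, 8.0, 1.0)
            target = r / np.sqrt(2)
            assert target / (grid_step * 1.001) <= sigma <= target * grid_step * 1.001

    def test_intensity_scaling_invariance(self):
        rng = np.random.default_rng(6)
        img = blob_image(3.0, spaced_centers(rng, 8, 25, 195, 35))
        assert optimal_log_scale(img, 8.0, 1.0) == optimal_log_scale(2 * img, 8.0, 1.0)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            optimal_log_scale(np.full((50, 50), 3.0), 8.0)


def nucleus_stack(centers_um, px=1.3, dz=10.0, shape=(12, 96, 96), peak=500.0, bg=100.0, seed=0):
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    vol = np.full(shape, bg)
    for cx, cy, cz in centers_um:
        q = (
            ((xx * px - cx) ** 2 + (yy * px - cy) ** 2) / (2 * 3.0**2)
            + ((zz * dz - cz) ** 2) / (2 * 4.0**2)
        )
        vol += peak * np.exp(-q)
    vol += rng.normal(0, 5.0, shape)
    return ImageStack(vol.clip(0), px, dz)


class TestDetectSpots:
    def test_single_nucleus_found_once(self):
        stack = nucleus_stack([(62.4, 62.4, 60.0)])
        found = detect_spots(
            stack, SpotParams(scale_sigma=3.0, mode="3d"), intensity_threshold=200.0
        )
        assert len(found) == 1
        s = found[0]
        dist = np.sqrt((s.x - 62.4) ** 2 + (s.y - 62.4) ** 2 + (s.z - 60.0) ** 2)
        assert dist <= 8.0

    def test_merge_distance_rule(self):
        # separated by 3 x max_spot_radius -> two spots
        far = nucleus_stack([(40.0, 60.0, 60.0), (64.0, 60.0, 60.0)])
        assert len(
            detect_spots(far, SpotParams(scale_sigma=3.0, mode="3d"),
                         intensity_threshold=200.0)
        ) == 2
        # separated by 0.3 x max_spot_radius -> one spot
        near = nucleus_stack([(60.0, 60.0, 60.0), (62.4, 60.0, 60.0)])
        assert len(
            detect_spots(near, SpotParams(scale_sigma=3.0, mode="3d"),
                         intensity_threshold=200.0)
        ) == 1

    def test_noise_only_scene_with_bright_threshold(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(100, 10, size=(10, 64, 64)).clip(0)
        found = detect_spots(
            ImageStack(vol, 1.3, 10.0),
            SpotParams(scale_sigma=3.0, mode="3d"),
            intensity_threshold=400.0,
        )
        assert found == []

    def test_25d_reads_z_from_height_view(self):
        stack = nucleus_stack([(62.4, 62.4, 70.0)])
        found = detect_spots(
            stack, SpotParams(scale_sigma=3.0, mode="2.5d"), intensity_threshold=200.0
        )
        assert len(found) == 1
        assert found[0].mode == "2.5d"
        assert abs(found[0].z - 70.0) <= 10.0  # one z-step

    def test_merging_is_idempotent(self):
        rng = np.random.default_rng(3)
        spots = [
            Spot(x, y, z, 1.0, response=-r)
            for x, y, z, r in rng.uniform(0, 100, size=(40, 4))
        ]
        once = merge_close_spots(spots, 8.0)
        twice = merge_close_spots(once, 8.0)
        assert [(s.x, s.y, s.z) for s in once] == [(s.x, s.y, s.z) for s in twice]

    def test_median_mask_intensity(self):
        mip = np.arange(25, dtype=float).reshape(5, 5)
        labels = np.zeros((5, 5), int)
        labels[0, :3] = 1
        assert median_mask_intensity(mip, labels) == 1.0
        with pytest.raises(ValueError):
            median_mask_intensity(mip, np.zeros((5, 5), int))


def half_context(label=1, a=40.0, b=40.0, c=40.0, depth=60.0, z_c=100.0):
    e = Ellipsoid3D(50.0, 50.0, z_c, a, b, c)
    ctx = SpheroidContext(
        label=label, ellipsoid=e, visibility=Visibility.HALF,
        z_top=z_c - c, depth=depth,
    )
    return e, [ctx]


class TestAssignAndCount:
    def _labels(self, shape=(100, 100)):
        labels = np.zeros(shape, int)
        labels[20:80, 20:80] = 1
        return labels

    def _spots(self, zs):
        return [Spot(50.0, 50.0, z, 10.0, response=-1.0) for z in zs]

    def test_full_visibility_counts_raw(self):
        e = Ellipsoid3D(50, 50, 100, 40, 40, 40)
        ctx = [SpheroidContext(1, e, Visibility.FULL, 60.0, 200.0)]
        counts, unassigned = assign_and_count(
            self._spots([70] * 10), ctx, self._labels(), 1.0
        )
        assert counts[1].corrected_count == 10
        assert unassigned == 0

    def test_half_visibility_doubles_at_depth_c(self):
        e, ctx = half_context(depth=40.0)  # depth == c -> factor 2
        counts, _ = assign_and_count(self._spots([70, 75, 80, 85, 90, 95, 100]),
                                     ctx, self._labels(), 1.0)
        assert counts[1].analyzable_count == 7
        assert counts[1].corrected_count == pytest.approx(14.0)

    def test_half_visibility_cap_scaling(self):
        e, ctx = half_context(depth=60.0)  # 1.5 c
        counts, _ = assign_and_count(self._spots([70, 90, 110, 130]),
                                     ctx, self._labels(), 1.0)
        factor = ellipsoid_volume(e) / ellipsoid_cap_volume(e.a, e.b, e.c, 60.0)
        # spots at z <= z_top + depth = 120: three of four
        assert counts[1].analyzable_count == 3
        assert counts[1].corrected_count == pytest.approx(3 * factor)
        assert counts[1].corrected_count >= counts[1].analyzable_count

    def test_not_analyzable_is_flagged_not_counted(self):
        e = Ellipsoid3D(50, 50, 100, 40, 40, 40)
        ctx = [SpheroidContext(1, e, Visibility.NOT_ANALYZABLE, 60.0, 20.0)]
        spots = self._spots([70, 80])
        counts, _ = assign_and_count(spots, ctx, self._labels(), 1.0)
        assert counts[1].corrected_count is None
        assert counts[1].raw_count == 2
        assert all(s.in_analyzable_region is False for s in spots)

    def test_baseline_mode_ignores_attenuation(self):
        e, ctx = half_context(depth=60.0)
        counts, _ = assign_and_count(self._spots([70, 90, 110, 130]),
                                     ctx, self._labels(), 1.0, baseline_2d=True)
        assert counts[1].corrected_count == 4

    def test_spots_outside_masks_are_unassigned(self):
        e, ctx = half_context()
        spots = [Spot(5.0, 5.0, 50.0, 1.0, response=-1.0)]
        counts, unassigned = assign_and_count(spots, ctx, self._labels(), 1.0)
        assert unassigned == 1
        assert spots[0].spheroid_label is None
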