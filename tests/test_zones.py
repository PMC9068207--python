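"""Zone segmentation, overlay scoring and contact-pair detection."""

import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

from trapscope import (
    ImageChannel,
    SceneParams,
    ValidationError,
    ZoneMap,
    atrous_decompose,
    contact_pairs,
    generate_scene,
    overlay_contact,
    rescale_image,
    segment_zones,
    select_scales,
    significant_coefficients,
)
from trapscope.pipeline import detect_zones


def disk_channel(radius_px=10, size=96, peak=100.0, center=None, pixel_size=1.0):
    center = center or (size // 2, size // 2)
    yy, xx = np.mgrid[:size, :size]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px ** 2
    return ImageChannel(disk * peak + 1.0, pixel_size), disk


def zones_of(channel, **kw):
    decomp = atrous_decompose(channel, 4)
    mask = significant_coefficients(decomp, k=3.0, sigma_mode="per-scale")
    return segment_zones(channel, mask, **kw)


class TestSegmentZones:
    def test_empty_mask_gives_zero_zones(self):
        chan = ImageChannel(np.full((64, 64), 5.0), 1.0)
        decomp = atrous_decompose(chan, 3)
        mask = significant_coefficients(decomp, k=3.0)
        zm = segment_zones(chan, mask, min_area_um2=0.0)
        assert zm.n_zones == 0

    def test_planted_disk_centroid_recovered(self):
        chan, disk = disk_channel(radius_px=10)
        zm = zones_of(chan, min_area_um2=0.0)
        assert zm.n_zones == 1
        cr, cc = zm.zones[0].centroid_rc
        assert abs(cr - 48) <= 1.0 and abs(cc - 48) <= 1.0

    def test_min_area_filter_removes_small_zones(self):
        size = 128
        yy, xx = np.mgrid[:size, :size]
        img = np.ones((size, size))
        for cy in (32, 96):  # two ~80 px^2 disks (radius 5)
            img[(yy - cy) ** 2 + (xx - 64) ** 2 <= 25] = 100.0
        chan = ImageChannel(img, 1.0)
        assert zones_of(chan, min_area_um2=100.0).n_zones == 0
        assert zones_of(chan, min_area_um2=50.0).n_zones == 2

    def test_scales_used_validated(self):
        chan, _ = disk_channel()
        decomp = atrous_decompose(chan, 3)
        mask = significant_coefficients(decomp)
        with pytest.raises(ValidationError):
            segment_zones(chan, mask, scales_used={5})

    def test_area_conservation(self):
        chan, _ = disk_channel()
        zm = zones_of(chan, min_area_um2=0.0)
        assert sum(z.area_px for z in zm.zones) == int((zm.labels > 0).sum())
        for z in zm.zones:
            assert z.area_um2 == pytest.approx(z.area_px * chan.pixel_area_um2)

    def test_halfmax_refinement_removes_psf_dilation(self):
        """Refined zone area tracks the true disk area; raw support is larger."""
        from scipy.ndimage import gaussian_filter

        size = 96
        yy, xx = np.mgrid[:size, :size]
        disk = (yy - 48) ** 2 + (xx - 48) ** 2 <= 100
        rng = np.random.default_rng(0)
        img = gaussian_filter(disk * 100.0, 2.0) + 5 + rng.normal(0, 2, disk.shape)
        chan = ImageChannel(np.clip(img, 0, None), 1.0)
        decomp = atrous_decompose(chan, 4)
        mask = significant_coefficients(decomp, k=3.0, sigma_mode="per-scale")
        raw = segment_zones(chan, mask, min_area_um2=0.0, scales_used={3, 4})
        refined = segment_zones(chan, mask, min_area_um2=0.0, scales_used={3, 4},
                                refine="halfmax")
        true_area = disk.sum()
        assert raw.support.sum() > 1.2 * true_area
        assert abs(refined.support.sum() - true_area) / true_area < 0.15


class TestSelectScales:
    @pytest.mark.parametrize("pixel_size, expected", [
        (0.5, {2, 3}), (0.25, {3, 4}), (1.0, {1, 2}),
    ])
    def test_physical_band_tracks_pixel_size(self, pixel_size, expected):
        assert select_scales(pixel_size, 4) == expected

    def test_falls_back_to_coarsest(self):
        assert select_scales(100.0, 4) == {4}


class TestOverlayContact:
    def test_self_overlap_is_total(self, contact_scene):
        chan = contact_scene.image.channel("CD8")
        zm = detect_zones(chan)
        res = overlay_contact(chan, zm, chan, zm)
        assert res.overlay_area_um2 == pytest.approx(zm.total_area_um2)
        assert res.contact_fraction_B == 1.0
        assert res.manders_A == pytest.approx(1.0)

    def test_disjoint_zones_score_zero(self):
        chan_a, _ = disk_channel(center=(24, 24), radius_px=8)
        chan_b, _ = disk_channel(center=(72, 72), radius_px=8)
        za = zones_of(chan_a, min_area_um2=0.0)
        zb = zones_of(chan_b, min_area_um2=0.0)
        res = overlay_contact(chan_a, za, chan_b, zb)
        assert res.overlay_area_um2 == 0.0
        assert res.contact_score == 0.0
        assert res.n_contacting_pairs == 0

    def test_symmetry_under_channel_swap(self, contact_scene):
        a = contact_scene.image.channel("CD8")
        b = contact_scene.image.channel("NPM")
        za, zb = detect_zones(a), detect_zones(b)
        ab = overlay_contact(a, za, b, zb)
        ba = overlay_contact(b, zb, a, za)
        assert ab.overlay_area_um2 == pytest.approx(ba.overlay_area_um2)
        assert ab.n_contacting_pairs == ba.n_contacting_pairs

    def test_overlay_invariants(self, contact_scene):
        a = contact_scene.image.channel("CD8")
        b = contact_scene.image.channel("NPM")
        res = overlay_contact(a, detect_zones(a), b, detect_zones(b))
        assert res.overlay_area_um2 <= min(res.zone_area_A_um2, res.zone_area_B_um2)
        assert res.contact_score >= 0
        assert 0 <= res.contact_fraction_B <= 1
        assert res.n_contacting_pairs <= res.n_objects_A * res.n_objects_B

    def test_overlay_area_tracks_planted_overlap(self):
        """Measured dual-positive area within 10% of ground truth."""
        scene = generate_scene(SceneParams(seed=7, target_contact_fraction=0.5))
        a = scene.image.channel("CD8")
        b = scene.image.channel("NPM")
        res = overlay_contact(a, detect_zones(a), b, detect_zones(b))
        assert res.overlay_area_um2 == pytest.approx(
            scene.true_overlap_area_um2, rel=0.10
        )

    def test_shape_mismatch_rejected(self, contact_scene):
        a = contact_scene.image.channel("CD8")
        za = detect_zones(a)
        small = ImageChannel(np.ones((32, 32)), 0.5)
        with pytest.raises(ValidationError):
            overlay_contact(a, za, small, zones_of(small, min_area_um2=0.0))


class TestContactPairs:
    def test_empty_b_gives_empty_list(self):
        chan, _ = disk_channel()
        za = zones_of(chan, min_area_um2=0.0)
        zb = ZoneMap.from_labels(np.zeros((96, 96), dtype=int), 1.0)
        assert contact_pairs(za, zb, 1.0) == []

    def test_planted_touching_pairs_exactly_recovered(self):
        scene = generate_scene(
            SceneParams(seed=5, n_cells_B=10, target_contact_fraction=0.3)
        )
        za = ZoneMap.from_labels(scene.truth_masks["CD8"],
                                 scene.image.pixel_size_um)
        zb = ZoneMap.from_labels(scene.truth_masks["NPM"],
                                 scene.image.pixel_size_um)
        pairs = contact_pairs(za, zb, max_gap_um=1.0)
        assert sorted(pairs) == sorted(scene.true_pairs)
        assert len(pairs) == 3

    def test_gap_threshold_is_sharp(self):
        """Pairing flips exactly at the boundary-gap distance, checked
        against a brute-force pairwise pixel-distance oracle."""
        labels_a = np.zeros((64, 64), dtype=int)
        labels_b = np.zeros((64, 64), dtype=int)
        labels_a[30:34, 10:20] = 1
        labels_b[30:34, 28:38] = 1
        px = 1.0
        pa = np.argwhere(labels_a > 0)
        pb = np.argwhere(labels_b > 0)
        d_min = min(np.hypot(*(a - b)) for a in pa for b in pb)
        gap = max(0.0, d_min - np.sqrt(2)) * px
        za = ZoneMap.from_labels(labels_a, px)
        zb = ZoneMap.from_labels(labels_b, px)
        assert contact_pairs(za, zb, max_gap_um=gap - 0.1) == []
        assert contact_pairs(za, zb, max_gap_um=gap + 0.1) == [(1, 1)]

    def test_adjacency_counts_at_zero_gap(self):
        labels_a = np.zeros((32, 32), dtype=int)
        labels_b = np.zeros((32, 32), dtype=int)
        labels_a[10:15, 10:15] = 1
        labels_b[15:20, 15:20] = 1  # diagonal 8-adjacency at (14,14)/(15,15)
        za = ZoneMap.from_labels(labels_a, 1.0)
        zb = ZoneMap.from_labels(labels_b, 1.0)
        assert contact_pairs(za, zb, max_gap_um=0.0) == [(1, 1)]

    def test_negative_gap_rejected(self):
        zm = ZoneMap.from_labels(np.zeros((32, 32), dtype=int), 1.0)
        with pytest.raises(ValidationError):
            contact_pairs(zm, zm, max_gap_um=-1.0)


class TestRescale:
    def test_identity_factor(self, contact_scene):
        chan = contact_scene.image.channel("CD8")
        out = rescale_image(chan, 1.0)
        assert out.pixel_size_um == chan.pixel_size_um
        np.testing.assert_array_equal(out.pixels, chan.pixels)

    def test_pixel_size_halved_at_factor_two(self, contact_scene):
        chan = contact_scene.image.channel("CD8")
        out = rescale_image(chan, 2.0)
        assert out.pixel_size_um == pytest.approx(chan.pixel_size_um / 2)
        assert out.shape == (2 * chan.shape[0], 2 * chan.shape[1])

    def test_round_trip_preserves_extent(self, contact_scene):
        chan = contact_scene.image.channel("CD8")
        back = rescale_image(rescale_image(chan, 2.0), 0.5)
        assert back.shape == chan.shape
        assert back.pixel_size_um == pytest.approx(chan.pixel_size_um)

    def test_degenerate_output_rejected(self):
        chan = ImageChannel(np.ones((16, 16)), 1.0)
        with pytest.raises(ValidationError):
            rescale_image(chan, 0.1)


class TestExports:
    def test_zone_labels_tiff_roundtrip(self, tmp_path, contact_scene):
        import tifffile
        from trapscope.zones import export_zone_labels

        zones = detect_zones(contact_scene.image.channel("CD8"))
        path = tmp_path / "labels.tiff"
        export_zone_labels(zones, path)
        back = tifffile.imread(path)
        np.testing.assert_array_equal(back, zones.labels.astype(np.uint16))

    def test_decomposition_tiff_pages(self, tmp_path):
        import tifffile
        from trapscope import atrous_decompose
        from trapscope.wavelet import export_decomposition

        rng = np.random.default_rng(0)
        d = atrous_decompose(rng.uniform(0, 100, (32, 32)), 3)
        path = tmp_path / "decomp.tiff"
        export_decomposition(d, path)
        back = tifffile.imread(path)
        assert back.shape == (4, 32, 32)
        np.testing.assert_allclose(back.sum(axis=0), sum(d.planes) + d.residual,
                                   rtol=1e-4, atol=1e-3)
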