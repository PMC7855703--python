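"""Superpixel sizing (ceiling rule), SLIC segmentation and patch extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import histomap as hm


class TestSizingRule:
    @pytest.mark.parametrize(
        "si,u,expected",
        [
            (64_000_000, 1500, 42_667),  # 8000x8000 slide at the default density
            (1500, 1500, 1),
            (1501, 1500, 2),
            (1, 1500, 1),
        ],
    )
    def test_known_values(self, si, u, expected):
        assert hm.superpixel_count(si, u) == expected

    @settings(derandomize=True, max_examples=200)
    @given(si=st.integers(1, 10**9), u=st.integers(1, 10**6))
    def test_ceiling_property(self, si, u):
        n = hm.superpixel_count(si, u)
        assert n >= 1
        assert (n - 1) * u < si <= n * u

    @settings(derandomize=True, max_examples=100)
    @given(u=st.integers(2, 3000), mult=st.integers(1, 50))
    def test_mean_area_within_one_of_target_for_large_images(self, u, mult):
        # for images of at least u^2 pixels the mean area lands in [u-1, u]
        si = u * u * mult
        n = hm.superpixel_count(si, u)
        assert u - 1 <= si / n <= u

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hm.superpixel_count(0, 1500)
        with pytest.raises(ValueError):
            hm.superpixel_count(100, 0)


class TestSlic:
    def test_constant_image_tiles_regularly(self):
        img = np.full((120, 120, 3), 127, dtype=np.uint8)
        seg = hm.segment_slic(img, 9)
        assert seg.n_superpixels == 9
        areas = np.array([r.pixel_count for r in seg.records])
        assert np.all(np.abs(areas - 1600) <= 0.2 * 1600)

    def test_two_color_halves_respected(self):
        img = np.zeros((128, 128, 3), dtype=np.uint8)
        img[:, :64] = (200, 60, 60)
        img[:, 64:] = (60, 60, 200)
        seg = hm.segment_slic(img, 16)
        for rec in seg.records:
            cols = np.where(seg.label_raster == rec.id)[1]
            left = (cols < 64).mean()
            assert min(left, 1 - left) <= 0.02

    def test_partition_and_connectivity_invariants(self, mosaic_segmentation):
        seg = mosaic_segmentation
        labels = seg.label_raster
        ids = np.array(sorted(r.id for r in seg.records))
        np.testing.assert_array_equal(ids, np.arange(seg.n_superpixels))
        assert sum(r.pixel_count for r in seg.records) == labels.size
        np.testing.assert_array_equal(np.unique(labels), ids)
        # 4-connectivity of each superpixel
        from scipy.ndimage import label as cc_label

        for rec in seg.records[:: max(1, seg.n_superpixels // 25)]:
            _, n_components = cc_label(labels == rec.id)
            assert n_components == 1
        # centroid inside bounding box
        for rec in seg.records:
            r0, c0, r1, c1 = rec.bounding_box
            assert r0 <= rec.centroid[0] < r1
            assert c0 <= rec.centroid[1] < c1

    def test_achieved_count_near_target(self, mosaic, mosaic_segmentation):
        target = hm.superpixel_count(mosaic.image.shape[0] * mosaic.image.shape[1])
        achieved = mosaic_segmentation.n_superpixels
        assert abs(achieved - target) <= 0.15 * target

    def test_determinism(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, (96, 96, 3), dtype=np.uint8)
        a = hm.segment_slic(img, 6)
        b = hm.segment_slic(img, 6)
        np.testing.assert_array_equal(a.label_raster, b.label_raster)

    def test_too_many_superpixels_rejected(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            hm.segment_slic(img, 17)


class TestPatchExtraction:
    def _single_superpixel_seg(self, h, w):
        labels = np.zeros((h, w), dtype=np.int32)
        from histomap.superpixels import _records_from_labels

        return hm.SuperpixelSegmentation(labels, _records_from_labels(labels))

    def test_bounding_box_resized_to_requested_side(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (40, 60, 3), dtype=np.uint8)
        seg = self._single_superpixel_seg(40, 60)
        ds = hm.extract_patches(img, seg, side=56)
        assert ds.patches.shape == (1, 56, 56, 3)

    def test_exact_size_crop_is_returned_verbatim(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (56, 56, 3), dtype=np.uint8)
        seg = self._single_superpixel_seg(56, 56)
        ds = hm.extract_patches(img, seg, side=56)
        np.testing.assert_array_equal(ds.patches[0], img)

    def test_one_pixel_superpixel_yields_constant_patch(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 0] = (10, 200, 30)
        img[0, 1] = (1, 2, 3)
        img[1, 0] = (4, 5, 6)
        img[1, 1] = (7, 8, 9)
        labels = np.array([[0, 1], [2, 3]], dtype=np.int32)
        from histomap.superpixels import _records_from_labels

        seg = hm.SuperpixelSegmentation(labels, _records_from_labels(labels))
        ds = hm.extract_patches(img, seg, side=56)
        assert (ds.patches[0] == np.array([10, 200, 30], dtype=np.uint8)).all()

    def test_order_stable_and_deterministic(self, mosaic, mosaic_segmentation):
        a = hm.extract_patches(mosaic.image, mosaic_segmentation, side=56)
        b = hm.extract_patches(mosaic.image, mosaic_segmentation, side=56)
        np.testing.assert_array_equal(a.patches, b.patches)
        np.testing.assert_array_equal(a.source_ids, np.arange(len(a)))

    def test_unusual_side_requires_override(self, mosaic, mosaic_segmentation):
        with pytest.raises(ValueError):
            hm.extract_patches(mosaic.image, mosaic_segmentation, side=64)
        ds = hm.extract_patches(
            mosaic.image, mosaic_segmentation, side=16, allow_any_side=True
        )
        assert ds.side == 16


class TestPhysicalSize:
    @pytest.mark.parametrize(
        "area,um,expected,tol",
        [
            (51 * 51, 2.3, 117.3, 0.05),  # printed equivalence: ~117 um side
            (1, 1, 1.0, 1e-12),
            (1500, 2.016, 78.08, 0.01),
        ],
    )
    def test_values(self, area, um, expected, tol):
        assert hm.physical_superpixel_size(area, um) == pytest.approx(expected, abs=tol)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hm.physical_superpixel_size(0, 2.0)


def test_segmentation_roundtrip_via_tiff_and_csv(tmp_path, mosaic_segmentation):
    mosaic_segmentation.save(tmp_path)
    back = hm.SuperpixelSegmentation.load(tmp_path)
    np.testing.assert_array_equal(back.label_raster, mosaic_segmentation.label_raster)
    assert [r.id for r in back.records] == [r.id for r in mosaic_segmentation.records]
    assert [r.bounding_box for r in back.records] == [
        r.bounding_box for r in mosaic_segmentation.records
    ]
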