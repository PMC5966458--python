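"""Segmentation chain: operator behavior against brute-force morphology oracles."""

import numpy as np
import pytest
from scipy import ndimage

from invadopipe.image import CalibratedImage
from invadopipe.segmentation import (
    DegenerateHistogramError,
    SegmentationParams,
    auto_threshold,
    filter_regions,
    isodata_threshold,
    label_regions,
    median_filter,
    refine_mask,
    rolling_ball_subtract,
    segment_rosettes,
    split_red_channel,
)
from conftest import constant_image


def _img(arr, px=1.0):
    return CalibratedImage(np.asarray(arr, dtype=float), px)


class TestSplitRedChannel:
    def test_pure_red_image(self):
        rgb = np.zeros((8, 8, 3)); rgb[..., 0] = 200
        out = split_red_channel(CalibratedImage(rgb, 0.5, channel="rgb"))
        assert np.all(out.pixels == 200) and out.pixel_size_um == 0.5

    def test_selects_red_not_max(self):
        rgb = np.zeros((4, 4, 3)); rgb[1, 2] = (10, 250, 250)
        out = split_red_channel(CalibratedImage(rgb, 1.0))
        assert out.pixels[1, 2] == 10

    def test_grayscale_rejected(self):
        with pytest.raises(ValueError):
            split_red_channel(constant_image())


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = constant_image(37.0)
        assert np.array_equal(median_filter(img, 2).pixels, img.pixels)

    def test_hot_pixel_removed_at_radius_2(self):
        arr = np.zeros((21, 21)); arr[10, 10] = 255
        out = median_filter(_img(arr), 2)
        assert out.pixels[10, 10] == 0.0

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        arr = rng.random((16, 16))
        assert np.array_equal(median_filter(_img(arr), 0).pixels, arr)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            median_filter(constant_image(), -1)


class TestRollingBall:
    def test_constant_maps_to_zero(self):
        out = rolling_ball_subtract(constant_image(100.0), 20)
        assert np.all(out.pixels == 0.0)

    def test_output_never_exceeds_input(self):
        rng = np.random.default_rng(1)
        arr = rng.random((48, 48)) * 50 + 20
        out = rolling_ball_subtract(_img(arr), 10)
        assert np.all(out.pixels <= arr + 1e-9) and np.all(out.pixels >= 0)

    def test_disk_amplitude_recovered_over_flat_background(self):
        yy, xx = np.mgrid[0:80, 0:80]
        disk = np.hypot(xx - 40, yy - 40) <= 3
        arr = np.full((80, 80), 100.0); arr[disk] += 50
        out = rolling_ball_subtract(_img(arr), 20)
        assert out.pixels[disk].max() == pytest.approx(50.0, rel=0.05)

    def test_small_features_on_zero_background_preserved(self):
        yy, xx = np.mgrid[0:80, 0:80]
        disk = np.hypot(xx - 40, yy - 40) <= 3
        arr = np.zeros((80, 80)); arr[disk] = 50
        out = rolling_ball_subtract(_img(arr), 20)
        assert np.abs(out.pixels - arr).max() < 0.01 * 50

    def test_matches_bruteforce_ball_opening(self):
        """Background equals grayscale opening with a spherical element."""
        r = 10
        by, bx = np.mgrid[-r : r + 1, -r : r + 1]
        ball = np.where(
            bx**2 + by**2 <= r**2,
            np.sqrt(np.maximum(r**2 - bx**2 - by**2, 0.0)) - r,
            -np.inf,
        )
        rng = np.random.default_rng(2)
        arr = ndimage.gaussian_filter(rng.random((60, 60)) * 80 + 40, 3)
        opened = ndimage.grey_dilation(ndimage.grey_erosion(arr, structure=ball), structure=ball)
        out = rolling_ball_subtract(_img(arr), r)
        # edge padding policies differ; compare away from the border
        core = (slice(r, -r), slice(r, -r))
        assert np.abs((arr - out.pixels) - opened)[core].max() < 1.0

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            rolling_ball_subtract(constant_image(), 0)


class TestAutoThreshold:
    def test_two_valued_image_perfectly_separated(self):
        arr = np.zeros((10, 10)); arr.ravel()[:50] = 255
        mask = auto_threshold(_img(arr))
        assert mask.sum() == 50 and np.all(arr[mask] == 255)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            auto_threshold(constant_image())

    def test_isodata_fixed_point_property(self):
        """The returned threshold is a fixed point of the intermeans update."""
        rng = np.random.default_rng(3)
        pix = np.concatenate([rng.normal(10, 3, 5000), rng.normal(100, 5, 500)])
        t = isodata_threshold(pix)
        assert t == pytest.approx((pix[pix <= t].mean() + pix[pix > t].mean()) / 2, abs=1e-4)
        assert 20 < t < 90  # lies between the classes, not inside either mode

    def test_false_positive_rate_below_one_percent_on_synthetic_field(self, clean_field):
        img, truth = clean_field
        filtered = rolling_ball_subtract(median_filter(img, 2), 20)
        mask = auto_threshold(filtered)
        background = truth.label_mask == 0
        fp_rate = (mask & background).sum() / background.sum()
        assert fp_rate < 0.01

    def test_otsu_method_selectable(self):
        arr = np.zeros((10, 10)); arr.ravel()[:30] = 200
        assert auto_threshold(_img(arr), "otsu").sum() == 30


class TestRefineMask:
    def test_annulus_filled_to_disk(self):
        yy, xx = np.mgrid[0:32, 0:32]
        rr = np.hypot(xx - 16, yy - 16)
        ring = (rr <= 10) & (rr >= 8)
        out = refine_mask(ring, 1)
        # brute-force oracle: closing with the 3x3 plus element, then fill
        struct = ndimage.generate_binary_structure(2, 1)
        oracle = ndimage.binary_fill_holes(
            ndimage.binary_erosion(ndimage.binary_dilation(ring, struct), struct, border_value=1)
        )
        assert np.array_equal(out, oracle)
        assert out[16, 16]  # the core is filled

    def test_solid_disk_unchanged(self):
        yy, xx = np.mgrid[0:32, 0:32]
        disk = np.hypot(xx - 16, yy - 16) <= 9
        assert np.array_equal(refine_mask(disk, 1), disk)

    def test_one_pixel_gap_closed_then_filled(self):
        # square annulus with a 4-px-thick wall and a 1-px break on the right
        ring = np.zeros((32, 32), dtype=bool)
        ring[6:26, 6:26] = True
        ring[10:22, 10:22] = False
        ring[16, 22:26] = False  # 1-px-tall gap through the wall
        out = refine_mask(ring, 1)
        assert out[16, 16]  # the enclosed core got filled despite the gap
        assert np.all(out >= ring)

    def test_idempotent_and_superset_on_random_masks(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            m = rng.random((40, 40)) < 0.35
            once = refine_mask(m, 1)
            assert np.array_equal(refine_mask(once, 1), once)
            assert np.all(once >= m)


class TestLabelAndFilter:
    def test_empty_mask(self):
        assert label_regions(np.zeros((10, 10), bool), 1.0) == []

    def test_connectivity_semantics(self):
        mask = np.zeros((10, 10), bool)
        mask[2:4, 2:4] = True
        mask[4:6, 4:6] = True  # touches only diagonally
        assert len(label_regions(mask, 1.0, connectivity=8)) == 1
        assert len(label_regions(mask, 1.0, connectivity=4)) == 2

    def test_filter_thresholds_as_published(self):
        params = SegmentationParams()
        mk = lambda a, c: type("R", (), {"area_um2": a, "circularity": c})()
        small_round = mk(9.5, 0.9)        # under the 10 um^2 floor
        big_bar = mk(40.0, 0.260)         # the 2x20 rectangle: fails circularity
        rosette = mk(28.3, 0.90)
        kept = filter_regions([small_round, big_bar, rosette], params)
        assert kept == [rosette]

    def test_filter_preserves_order_and_inclusive_bounds(self):
        params = SegmentationParams()
        mk = lambda a, c: type("R", (), {"area_um2": a, "circularity": c})()
        exactly_10 = mk(10.0, 0.5)
        exactly_035 = mk(50.0, 0.35)
        exactly_1 = mk(50.0, 1.0)
        assert filter_regions([exactly_10, exactly_035, exactly_1], params) == [
            exactly_10, exactly_035, exactly_1,
        ]


class TestSegmentRosettes:
    def test_constant_field_yields_nothing(self):
        assert segment_rosettes(constant_image()) == []

    def test_recovers_three_rosettes_with_disk_areas(self, clean_field):
        img, truth = clean_field
        regions = segment_rosettes(img)
        assert len(regions) == truth.rosette_count == 3
        expected = sorted(np.pi * (d / 2) ** 2 for d in truth.diameters_um)
        got = sorted(r.area_um2 for r in regions)
        for a, b in zip(got, expected):
            assert a == pytest.approx(b, rel=0.15)

    def test_fibers_rejected_by_circularity(self, field_with_fibers):
        img, truth = field_with_fibers
        regions = segment_rosettes(img)
        assert len(regions) == truth.rosette_count == 3

    def test_every_region_satisfies_configured_bounds(self, field_with_fibers):
        img, _ = field_with_fibers
        params = SegmentationParams()
        for r in segment_rosettes(img, params):
            assert r.area_um2 >= params.min_area_um2
            assert params.circularity_range[0] <= r.circularity <= params.circularity_range[1]

    def test_rgb_input_uses_red_channel(self, clean_field):
        img, truth = clean_field
        rgb = np.zeros(img.pixels.shape + (3,))
        rgb[..., 0] = img.pixels
        rgb[..., 1] = 200.0  # bright uniform green must be ignored
        regions = segment_rosettes(CalibratedImage(rgb, img.pixel_size_um, channel="rgb"))
        assert len(regions) == truth.rosette_count
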