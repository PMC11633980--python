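import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from buscurate.image_model import BoundingBox, ScanImage
from buscurate.scan_filtering import (ColorMaskSpec, FilterParams, ScanMode,
                                      build_color_mask, classify_scan_mode,
                                      default_mask_specs, detect_indicator_shape,
                                      detect_invalid, flow_fraction)


def gray_scan(value, shape=(100, 100)):
    return ScanImage(np.full(shape, value, dtype=np.uint8))


class TestDetectInvalid:
    def test_all_black_invalid_all_bright_valid(self):
        assert detect_invalid(gray_scan(0))
        assert not detect_invalid(gray_scan(255))

    def test_threshold_is_strictly_greater(self):
        # exactly 75% black is NOT invalid
        px = np.full((100, 100), 200, dtype=np.uint8)
        px.flat[:7500] = 0
        assert not detect_invalid(ScanImage(px))
        # 76% of pixels at value 4 (< 5) is invalid
        px2 = np.full((100, 100), 200, dtype=np.uint8)
        px2.flat[:7600] = 4
        assert detect_invalid(ScanImage(px2))
        # value 5 is not black ("less than five" is strict)
        px3 = np.full((100, 100), 5, dtype=np.uint8)
        assert not detect_invalid(ScanImage(px3))

    def test_scan_area_restriction(self):
        px = np.full((100, 100), 200, dtype=np.uint8)
        px[:, :50] = 0  # left half black
        assert not detect_invalid(ScanImage(px))
        assert detect_invalid(ScanImage(px), scan_area=BoundingBox(0, 0, 50, 100))

    @given(hnp.arrays(np.uint8, (20, 20)), st.integers(0, 399))
    def test_monotone_under_blackening(self, px, flat_idx):
        scan = ScanImage(px.copy())
        before = detect_invalid(scan)
        px2 = px.copy()
        px2.flat[flat_idx] = 0
        after = detect_invalid(ScanImage(px2))
        assert after or not before  # blackening never flips True -> False


class TestColorMask:
    def test_gray_image_not_chromatic(self):
        mask = build_color_mask(gray_scan(128), default_mask_specs()["RED"])
        assert not mask.any()

    def test_dilated_point(self):
        px = np.zeros((21, 21, 3), dtype=np.uint8)
        px[10, 10] = (255, 0, 0)
        spec = default_mask_specs()["RED"]
        mask = build_color_mask(ScanImage(px), spec)
        assert mask[10, 10] and mask[10, 12] and mask[8, 10]
        assert not mask[10, 14]
        # dilation of a point = disk of the spec radius
        assert mask.sum() == 13  # |disk(2)|

    def test_blue_rectangle_covered(self):
        px = np.zeros((40, 60, 3), dtype=np.uint8)
        px[10:20, 20:40] = (0, 0, 255)
        mask = build_color_mask(ScanImage(px), default_mask_specs()["BLUE"])
        assert mask[10:20, 20:40].all()  # dilation superset of the painted box

    def test_hue_wrap_for_red(self):
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        px[0, 0] = (255, 0, 30)   # hue just below 0 wrap
        px[1, 1] = (255, 30, 0)   # hue just above 0
        spec = ColorMaskSpec("RED", (170, 80, 80), (10, 255, 255), dilation_radius=0)
        mask = build_color_mask(ScanImage(px), spec)
        assert mask[0, 0] and mask[1, 1]


class TestIndicatorShape:
    def test_empty_mask(self):
        assert not detect_indicator_shape(np.zeros((100, 100), dtype=bool))

    def test_complete_rectangle_border(self):
        mask = np.zeros((300, 400), dtype=bool)
        mask[50:52, 100:300] = True
        mask[248:250, 100:300] = True
        mask[50:250, 100:102] = True
        mask[50:250, 298:300] = True
        assert detect_indicator_shape(mask)

    def test_partial_rectangle_three_sides(self):
        mask = np.zeros((300, 400), dtype=bool)
        mask[50:52, 100:300] = True
        mask[50:250, 100:102] = True
        mask[50:250, 298:300] = True
        assert detect_indicator_shape(mask)

    def test_spanning_vertical_line(self):
        mask = np.zeros((200, 300), dtype=bool)
        mask[10:190, 150] = True  # 90% of height
        assert detect_indicator_shape(mask)

    def test_dotted_spanning_line_within_gap_tolerance(self):
        mask = np.zeros((200, 300), dtype=bool)
        for y in range(10, 190, 8):
            mask[y:y + 4, 150] = True  # 4 on, 4 off: gaps <= 5 tolerated
        assert detect_indicator_shape(mask)

    def test_small_blob_rejected(self):
        mask = np.zeros((300, 400), dtype=bool)
        mask[100:105, 200:204] = True  # 20-pixel blob
        assert not detect_indicator_shape(mask)

    def test_small_square_below_min_rect_px_rejected(self):
        mask = np.zeros((300, 400), dtype=bool)
        mask[100:120, 200:220] = True  # crisp square, but tiny (text-glyph scale)
        assert not detect_indicator_shape(mask)


class TestFlowFraction:
    def test_extremes(self):
        box = BoundingBox(0, 0, 10, 10)
        assert flow_fraction(np.zeros((10, 10), dtype=bool), box) == 0.0
        assert flow_fraction(np.ones((10, 10), dtype=bool), box) == 1.0

    def test_block_fraction(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[20:30, 40:50] = True
        assert flow_fraction(mask, BoundingBox(0, 0, 100, 100)) == pytest.approx(0.01)

    def test_out_of_bounds_box(self):
        with pytest.raises(ValueError):
            flow_fraction(np.zeros((10, 10), dtype=bool), BoundingBox(0, 0, 20, 20))

    @given(hnp.arrays(np.bool_, (17, 23)))
    def test_matches_brute_force_count(self, mask):
        box = BoundingBox(3, 2, 20, 15)
        frac = flow_fraction(mask, box)
        count = sum(bool(mask[y, x]) for y in range(2, 15) for x in range(3, 20))
        assert frac == pytest.approx(count / (17 * 13))
        assert 0.0 <= frac <= 1.0


class TestClassifyScanMode:
    def test_grayscale_short_circuit(self, rng):
        px = rng.integers(0, 256, size=(50, 50), dtype=np.uint8)
        assert classify_scan_mode(ScanImage(px)) is ScanMode.B_MODE
        # 3-channel but chromatically flat: still B-mode
        flat = np.repeat(px[..., None], 3, axis=2)
        assert classify_scan_mode(ScanImage(flat)) is ScanMode.B_MODE

    def test_indicator_rectangle_fires_step3(self):
        px = np.full((300, 400, 3), 90, dtype=np.uint8)
        px[0, 0] = (91, 90, 90)  # break exact grayscaleness
        for sl in [(slice(50, 52), slice(100, 300)), (slice(248, 250), slice(100, 300)),
                   (slice(50, 250), slice(100, 102)), (slice(50, 250), slice(298, 300))]:
            px[sl] = (0, 220, 0)
        assert classify_scan_mode(ScanImage(px)) is ScanMode.NON_B_MODE

    def test_flow_fraction_fires_step4(self, rng):
        px = np.full((100, 100, 3), 90, dtype=np.uint8)
        px[0, 0] = (91, 90, 90)
        ys, xs = np.unravel_index(
            rng.choice(10000, size=200, replace=False), (100, 100))
        px[ys, xs] = (200, 30, 30)  # 2% saturated red
        assert classify_scan_mode(ScanImage(px)) is ScanMode.NON_B_MODE

    def test_sparse_color_below_cutoff_is_b_mode(self, rng):
        px = np.full((300, 400, 3), 90, dtype=np.uint8)
        ys = rng.choice(300, size=30)
        xs = rng.choice(400, size=30)
        px[ys, xs] = (200, 30, 30)  # far below 0.5% after dilation
        assert classify_scan_mode(ScanImage(px)) is ScanMode.B_MODE
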