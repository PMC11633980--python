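import numpy as np
import pytest

from buscurate.image_model import BoundingBox, ScanImage
from buscurate.scan_cropping import (CropParams, DegenerateScanError, ShapeClass,
                                     classify_shape, crop, stage1_crop, stage2_crop)
from buscurate.synthetic_fixtures import build_class_spec, render_phantom


def block_scan(h=200, w=300, box=(40, 50, 190, 150), value=120):
    """Black frame with one bright block; box = (x_left, y_top, x_right, y_bottom)."""
    px = np.zeros((h, w), dtype=np.uint8)
    l, t, r, b = box
    px[t:b, l:r] = value
    return ScanImage(px)


class TestStage1:
    def test_tight_box_of_single_block(self):
        scan = block_scan()
        box, component = stage1_crop(scan)
        assert (box.x_left, box.y_top, box.x_right, box.y_bottom) == (40, 50, 190, 150)
        # opening rounds the corners; the interior must survive intact
        assert component[53:147, 43:187].all()
        assert not component[:50].any() and not component[150:].any()

    def test_largest_of_two_components_wins(self):
        px = np.zeros((200, 300), dtype=np.uint8)
        px[50:100, 40:90] = 120    # 2500 px
        px[120:140, 200:215] = 120  # 300 px
        box, _ = stage1_crop(px_scan := ScanImage(px))
        assert (box.x_left, box.y_top, box.x_right, box.y_bottom) == (40, 50, 90, 100)

    def test_uniform_image_degenerate(self):
        with pytest.raises(DegenerateScanError):
            stage1_crop(ScanImage(np.zeros((50, 50), dtype=np.uint8)))

    def test_text_strokes_opened_away(self):
        scan = block_scan()
        px = scan.pixels.copy()
        px[10:14, 10:60] = 255  # thin burnt-in text stroke in the margin
        box, _ = stage1_crop(ScanImage(px))
        assert (box.x_left, box.y_top, box.x_right, box.y_bottom) == (40, 50, 190, 150)


class TestClassifyShape:
    def test_solid_rectangle(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:90, 20:80] = True
        box = BoundingBox(20, 10, 80, 90)
        assert classify_shape(mask, box) is ShapeClass.RECTANGULAR

    def test_trapezoid_half_top_width(self):
        # fill = (a+b)/2*h over b*h = 0.75 < 0.95
        h, w = 120, 120
        mask = np.zeros((200, 200), dtype=bool)
        for i in range(h):
            half = int(round((60 + 60 * i / (h - 1)) / 2))
            mask[40 + i, 100 - half:100 + half] = True
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        box = BoundingBox(int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)
        assert classify_shape(mask, box) is ShapeClass.NON_RECTANGULAR

    def test_corner_nicks_still_rectangular(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[10:90, 20:80] = True
        for dy, dx in [(10, 20), (10, 79), (89, 20), (89, 79)]:
            mask[dy, dx] = False
        box = BoundingBox(20, 10, 80, 90)
        assert classify_shape(mask, box) is ShapeClass.RECTANGULAR


def brute_force_stage2(gray, box, mode):
    """Independent per-pixel re-derivation of the thirds-slice rule."""
    sub = gray[box.y_top:box.y_bottom, box.x_left:box.x_right]
    nm = sub != mode
    h, w = sub.shape
    hb = [(0, h // 3), (h // 3, (2 * h) // 3), ((2 * h) // 3, h)]
    wb = [(0, w // 3), (w // 3, (2 * w) // 3), ((2 * w) // 3, w)]
    L, R, T, B = [], [], [], []
    for lo, hi in hb:
        cols = [x for x in range(w) if any(nm[y, x] for y in range(lo, hi))]
        L.append(cols[0] if cols else 0)
        R.append(cols[-1] if cols else w - 1)
    for lo, hi in wb:
        rows = [y for y in range(h) if any(nm[y, x] for x in range(lo, hi))]
        T.append(rows[0] if rows else 0)
        B.append(rows[-1] if rows else h - 1)
    med = lambda v: sorted(v)[1]
    return (box.x_left + med(L), box.y_top + med(T),
            box.x_left + med(R) + 1, box.y_top + med(B) + 1)


class TestStage2:
    def test_full_box_is_fixed_point(self):
        scan = block_scan(box=(40, 50, 190, 150))
        box = BoundingBox(40, 50, 190, 150)
        out = stage2_crop(scan, box, mode_value=0)
        assert (out.x_left, out.y_top, out.x_right, out.y_bottom) == (40, 50, 190, 150)

    def test_symmetric_trapezoid_takes_middle_band_width(self):
        # top width 60, bottom width 120, h=120 divisible by 3
        px = np.zeros((200, 200), dtype=np.uint8)
        h = 120
        for i in range(h):
            half = int(round((60 + 60 * i / (h - 1)) / 2))
            px[40 + i, 100 - half:100 + half] = 120
        scan = ScanImage(px)
        box, _ = stage1_crop(scan, erosion_radius=0, dilation_radius=0)
        out = stage2_crop(scan, box, mode_value=0)
        expected = brute_force_stage2(px, box, 0)
        assert (out.x_left, out.y_top, out.x_right, out.y_bottom) == expected
        # median of the three band extremes = the middle band's extremes
        assert box.x_left < out.x_left and out.x_right < box.x_right

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        px = (rng.random((40, 50)) < 0.1).astype(np.uint8) * 200
        if not px.any():
            px[20, 25] = 200
        box = BoundingBox(5, 4, 45, 36)
        scan = ScanImage(px)
        out = stage2_crop(scan, box, mode_value=0)
        assert (out.x_left, out.y_top, out.x_right, out.y_bottom) == \
            brute_force_stage2(px, box, 0)


class TestCrop:
    def test_rectangular_phantom_stage2_equals_stage1(self):
        scan, gt = render_phantom(build_class_spec("plain", 0, 9))  # rectangular
        res = crop(scan)
        assert res.shape_class is ShapeClass.RECTANGULAR
        assert res.stage2_box == res.stage1_box
        # stage-1 box matches the generator's scan area to morphology slack
        for got, want in [(res.stage1_box.x_left, gt.scan_area.x_left),
                          (res.stage1_box.y_top, gt.scan_area.y_top),
                          (res.stage1_box.x_right, gt.scan_area.x_right),
                          (res.stage1_box.y_bottom, gt.scan_area.y_bottom)]:
            assert abs(got - want) <= 3

    @pytest.mark.parametrize("i,shape", [(1, "TRAPEZOID"), (2, "CONVEX")])
    def test_non_rectangular_phantom_strictly_tightened(self, i, shape):
        scan, _ = render_phantom(build_class_spec("plain", i, 9))
        res = crop(scan)
        assert res.shape_class is ShapeClass.NON_RECTANGULAR
        assert res.stage1_box.contains(res.stage2_box)
        assert (res.stage2_box.x_left > res.stage1_box.x_left
                and res.stage2_box.x_right < res.stage1_box.x_right)

    def test_all_black_phantom_degenerate(self):
        with pytest.raises(DegenerateScanError):
            crop(ScanImage(np.zeros((100, 100), dtype=np.uint8)))

    def test_mirror_symmetry(self):
        scan, _ = render_phantom(build_class_spec("plain", 1, 9))  # trapezoid
        res = crop(scan)
        mirrored = ScanImage(scan.pixels[:, ::-1].copy())
        res_m = crop(mirrored)
        w = scan.width
        for box, box_m in [(res.stage1_box, res_m.stage1_box),
                           (res.stage2_box, res_m.stage2_box)]:
            assert abs(box_m.x_left - (w - box.x_right)) <= 1
            assert abs(box_m.x_right - (w - box.x_left)) <= 1
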