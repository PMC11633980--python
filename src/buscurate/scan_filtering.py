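"""Scan filtering: invalid-frame detection and B-mode vs non-B-mode triage.

Two filters remove frames that should never reach an AI training set:

* *Invalid* frames are predominantly black inside the scan area - machine
  malfunction, annotation-only captures, or near-empty frames.  The rule is a
  black-pixel fraction: more than ``black_fraction_cutoff`` (default 75%) of
  the area at grayscale value below ``black_value_cutoff`` (default 5).

* *Non-B-mode* frames carry a colored overlay: Color/Power Doppler blood-flow
  highlighting or an elastography stiffness map.  They are found by a
  four-step test: (1) chromatically flat frames are B-mode by definition;
  (2) HSV color masks for the vendor flow palettes and for the green/white
  indicator graphics are built and dilated; (3) complete or partial
  rectangles and image-spanning lines in the green/white mask mark the frame
  non-B-mode; (4) otherwise the frame is non-B-mode when the flow mask covers
  more than ``flow_fraction_cutoff`` (default 0.5%) of the scan area.

Vendor palettes differ, so every HSV range is configuration, not contract.
Hue is expressed on the half-degree scale 0-179 (the convention most imaging
toolkits use for 8-bit HSV), saturation and value on 0-255.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from skimage import measure
from skimage.morphology import dilation, disk

from .image_model import BoundingBox, ScanImage, is_grayscale, to_grayscale

__all__ = [
    "ScanMode",
    "ColorMaskSpec",
    "FilterParams",
    "default_mask_specs",
    "flow_mask_specs",
    "indicator_mask_spec",
    "detect_invalid",
    "build_color_mask",
    "detect_indicator_shape",
    "flow_fraction",
    "classify_scan_mode",
]


class ScanMode(str, Enum):
    B_MODE = "B_MODE"
    NON_B_MODE = "NON_B_MODE"


@dataclass(frozen=True)
class ColorMaskSpec:
    """One HSV in-range test plus a dilation radius.

    ``hsv_low``/``hsv_high`` are (hue, sat, val) with hue on 0-179.  A low
    hue greater than the high hue encodes a wrapped range (red straddles 0).
    ``extra_low``/``extra_high`` optionally union a second achromatic range
    (used by the green/white indicator spec for its white component).
    """

    name: str
    hsv_low: tuple[int, int, int]
    hsv_high: tuple[int, int, int]
    dilation_radius: int = 2
    extra_low: Optional[tuple[int, int, int]] = None
    extra_high: Optional[tuple[int, int, int]] = None


def default_mask_specs() -> dict[str, ColorMaskSpec]:
    """Default HSV palette: flow colors plus the green/white indicator."""
    sat_lo, val_lo = 80, 80
    return {
        "RED": ColorMaskSpec("RED", (170, sat_lo, val_lo), (10, 255, 255)),
        "ORANGE": ColorMaskSpec("ORANGE", (11, sat_lo, val_lo), (25, 255, 255)),
        "YELLOW": ColorMaskSpec("YELLOW", (26, sat_lo, val_lo), (34, 255, 255)),
        "GREEN": ColorMaskSpec("GREEN", (35, sat_lo, val_lo), (85, 255, 255)),
        "BLUE": ColorMaskSpec("BLUE", (100, sat_lo, val_lo), (130, 255, 255)),
        "GREEN_WHITE_INDICATOR": ColorMaskSpec(
            "GREEN_WHITE_INDICATOR",
            (35, sat_lo, val_lo),
            (85, 255, 255),
            extra_low=(0, 0, 220),
            extra_high=(179, 30, 255),
        ),
    }


def flow_mask_specs(specs: Optional[dict[str, ColorMaskSpec]] = None) -> list[ColorMaskSpec]:
    specs = specs or default_mask_specs()
    return [specs[k] for k in ("RED", "ORANGE", "YELLOW", "GREEN", "BLUE") if k in specs]


def indicator_mask_spec(specs: Optional[dict[str, ColorMaskSpec]] = None) -> ColorMaskSpec:
    specs = specs or default_mask_specs()
    return specs["GREEN_WHITE_INDICATOR"]


@dataclass
class FilterParams:
    black_value_cutoff: int = 5
    black_fraction_cutoff: float = 0.75
    flow_fraction_cutoff: float = 0.005
    grayscale_tol: int = 0
    span_fraction: float = 0.80
    span_gap_px: int = 5
    min_rect_extent: float = 0.5
    min_rect_px: int = 40

    def __post_init__(self) -> None:
        if not (0.0 < self.black_fraction_cutoff < 1.0):
            raise ValueError("black_fraction_cutoff must lie in (0, 1)")
        if not (0.0 < self.flow_fraction_cutoff < 1.0):
            raise ValueError("flow_fraction_cutoff must lie in (0, 1)")
        if not (0 <= self.black_value_cutoff <= 255):
            raise ValueError("black_value_cutoff must lie in [0, 255]")


def detect_invalid(
    scan: ScanImage,
    params: Optional[FilterParams] = None,
    scan_area: Optional[BoundingBox] = None,
) -> bool:
    """True when the (cropped) frame is mostly black.

    Both comparisons are strict: a pixel is black when its value is strictly
    below ``black_value_cutoff``, and the frame is invalid when the black
    fraction strictly exceeds ``black_fraction_cutoff``.
    """
    params = params or FilterParams()
    gray = to_grayscale(scan).pixels
    if scan_area is not None:
        gray = gray[scan_area.slices()]
    frac = float(np.mean(gray < params.black_value_cutoff))
    return frac > params.black_fraction_cutoff


def _rgb_to_hsv8(pixels: np.ndarray) -> np.ndarray:
    """RGB uint8 -> HSV with hue 0-179, sat/val 0-255 (integer grid)."""
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(pixels)
    out = np.empty(hsv.shape, dtype=np.float64)
    out[..., 0] = hsv[..., 0] * 180.0  # [0, 180)
    out[..., 1] = hsv[..., 1] * 255.0
    out[..., 2] = hsv[..., 2] * 255.0
    return out


def _in_range(hsv: np.ndarray, low: Sequence[int], high: Sequence[int]) -> np.ndarray:
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if low[0] <= high[0]:
        hue_ok = (h >= low[0]) & (h <= high[0])
    else:  # wrapped hue range (e.g. red)
        hue_ok = (h >= low[0]) | (h <= high[0])
    return hue_ok & (s >= low[1]) & (s <= high[1]) & (v >= low[2]) & (v <= high[2])


def build_color_mask(scan: ScanImage, spec: ColorMaskSpec) -> np.ndarray:
    """Binary H x W mask of pixels inside the spec's HSV range, dilated.

    A 1-channel scan yields an all-false mask for chromatic specs; the
    achromatic (white) component of a spec still applies, evaluated on the
    replicated gray values.
    """
    if scan.channels == 1:
        rgb = np.repeat(scan.pixels[..., None], 3, axis=2)
    else:
        rgb = scan.pixels
    hsv = _rgb_to_hsv8(rgb)
    mask = _in_range(hsv, spec.hsv_low, spec.hsv_high)
    if spec.extra_low is not None and spec.extra_high is not None:
        mask |= _in_range(hsv, spec.extra_low, spec.extra_high)
    if spec.dilation_radius > 0 and mask.any():
        mask = dilation(mask, disk(spec.dilation_radius))
    return mask


def _max_gapped_runs(mask: np.ndarray, gap: int) -> np.ndarray:
    """Per-column longest run of True pixels, tolerating gaps <= ``gap``."""
    if gap > 0:
        from scipy.ndimage import binary_closing

        structure = np.ones((gap + 1, 1), dtype=bool)
        mask = binary_closing(mask, structure=structure)
    run = np.zeros(mask.shape[1], dtype=np.int64)
    best = np.zeros(mask.shape[1], dtype=np.int64)
    for row in mask:
        run = (run + 1) * row
        np.maximum(best, run, out=best)
    return best


def _has_spanning_line(mask: np.ndarray, span_fraction: float, gap: int) -> bool:
    h, w = mask.shape
    if _max_gapped_runs(mask, gap).max(initial=0) >= span_fraction * h:
        return True
    return _max_gapped_runs(mask.T, gap).max(initial=0) >= span_fraction * w


def _interior_angles(poly: np.ndarray) -> np.ndarray:
    """Interior angle (degrees) at every vertex of a closed polygon."""
    prev = np.roll(poly, 1, axis=0)
    nxt = np.roll(poly, -1, axis=0)
    v1 = prev - poly
    v2 = nxt - poly
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > 0) & (n2 > 0)
    cosang = np.full(len(poly), 1.0)
    cosang[ok] = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def detect_indicator_shape(
    green_white_mask: np.ndarray,
    params: Optional[FilterParams] = None,
) -> bool:
    """Detect indicator graphics: box fragments or image-spanning lines.

    Fires on (a) a contour at least ``min_rect_px`` large in both dimensions
    whose Douglas-Peucker approximation has at least three near-right-angle
    vertices spreading over ``min_rect_extent`` of the contour's extent in at
    least one axis (partial boxes keep corners only along their closed side;
    the absolute minimum keeps text glyphs from registering); or (b) a
    gap-tolerant run of mask pixels spanning at least ``span_fraction`` of
    the image height or width.
    """
    params = params or FilterParams()
    mask = np.asarray(green_white_mask, dtype=bool)
    if not mask.any():
        return False
    if _has_spanning_line(mask, params.span_fraction, params.span_gap_px):
        return True
    for contour in measure.find_contours(mask.astype(float), 0.5):
        diffs = np.diff(contour, axis=0)
        perimeter = float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
        if perimeter < 4 * params.min_rect_px * params.min_rect_extent:
            continue
        # Tolerance is capped: a purely relative tolerance exceeds the stroke
        # width of long thin box outlines and collapses their corners.
        poly = measure.approximate_polygon(
            contour, tolerance=min(0.02 * perimeter, 8.0))
        if len(poly) > 1 and np.array_equal(poly[0], poly[-1]):
            poly = poly[:-1]
        if len(poly) < 3:
            continue
        angles = _interior_angles(poly)
        corners = poly[(angles >= 80.0) & (angles <= 100.0)]
        if len(corners) < 3:
            continue
        b_h = contour[:, 0].max() - contour[:, 0].min()
        b_w = contour[:, 1].max() - contour[:, 1].min()
        if b_h < params.min_rect_px or b_w < params.min_rect_px:
            continue  # text-glyph scale: not an indicator graphic
        c_h = corners[:, 0].max() - corners[:, 0].min()
        c_w = corners[:, 1].max() - corners[:, 1].min()
        # A 3-sided box keeps right angles only along its closed side, so the
        # corner spread need cover the contour's extent in one axis only.
        if (c_h >= params.min_rect_extent * b_h
                or c_w >= params.min_rect_extent * b_w):
            return True
    return False


def flow_fraction(flow_mask: np.ndarray, scan_area: BoundingBox) -> float:
    """Fraction of scan-area pixels covered by the flow mask."""
    mask = np.asarray(flow_mask, dtype=bool)
    h, w = mask.shape
    if not (
        0 <= scan_area.x_left < scan_area.x_right <= w
        and 0 <= scan_area.y_top < scan_area.y_bottom <= h
    ):
        raise ValueError("scan_area outside mask bounds")
    sub = mask[scan_area.slices()]
    return float(sub.sum()) / float(scan_area.area)


def classify_scan_mode(
    scan: ScanImage,
    params: Optional[FilterParams] = None,
    specs: Optional[dict[str, ColorMaskSpec]] = None,
    scan_area: Optional[BoundingBox] = None,
) -> ScanMode:
    """Four-step B-mode vs non-B-mode triage.

    ``scan_area`` should be the stage-1 crop box so the flow-fraction
    denominator is the scan area rather than the full frame; it defaults to
    the full frame when no crop is available.
    """
    params = params or FilterParams()
    specs = specs or default_mask_specs()
    # Step 1: chromatically flat frames are B-mode.
    if is_grayscale(scan, tol=params.grayscale_tol):
        return ScanMode.B_MODE
    # Step 2: build the dilated masks.
    indicator = build_color_mask(scan, indicator_mask_spec(specs))
    flow = np.zeros((scan.height, scan.width), dtype=bool)
    for spec in flow_mask_specs(specs):
        flow |= build_color_mask(scan, spec)
    # Step 3: indicator rectangles / spanning lines.
    if detect_indicator_shape(indicator, params):
        return ScanMode.NON_B_MODE
    # Step 4: flow coverage of the scan area.
    area = scan_area or scan.full_box()
    if flow_fraction(flow, area) > params.flow_fraction_cutoff:
        return ScanMode.NON_B_MODE
    return ScanMode.B_MODE
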