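"""Detection of lesion calipers and dual-view composite scans.

Calipers are sonographer-placed measurement marks (crosses, "X"s, numerals),
sometimes joined by a dotted line spanning the lesion.  The base detector
enhances the frame - the outer 15% of every side is blacked out so software
overlays and burnt-in text cannot masquerade as calipers, then an edge filter
and a maximum filter isolate compact bright marks - and keeps every contour
whose bounding box is between 10 and 70 pixels in both height and width.

That size gate is exactly why dotted spanning lines defeat the base method:
after the maximum filter and dilation the dots, the line and the end marks
fuse into one object far larger than 70 px.  The Hough extension recovers
these by running probabilistic line detection on the same enhanced image and
declaring a caliper when two detected segments intersect at a non-parallel
angle.  It is off by default; enable it per dataset when this annotation
style appears.

Dual-view scans store two views side by side in one frame.  They are found by
(1) vetoing frames whose teal/green mask fires (elastography), (2) vetoing
tall frames (width < 75% of height), (3) Canny edge detection, and (4)
testing that the midline column carries many more edge pixels than its
neighbors 10 columns away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageFilter
from skimage import measure
from skimage.feature import canny
from skimage.morphology import dilation, disk
from skimage.transform import probabilistic_hough_line

from .image_model import BoundingBox, ScanImage, to_grayscale
from .scan_filtering import ColorMaskSpec, build_color_mask, default_mask_specs

__all__ = [
    "CaliperParams",
    "DualViewParams",
    "detect_calipers",
    "detect_calipers_hough",
    "detect_dual_view",
]


@dataclass
class CaliperParams:
    border_mask_fraction: float = 0.15
    min_box_px: int = 10
    max_box_px: int = 70
    max_filter_size: int = 3
    dilation_radius: int = 2
    binarize_threshold: int = 60
    hough_enabled: bool = False
    hough_min_line_px: int = 15
    hough_line_gap_px: int = 4
    hough_threshold: int = 10
    hough_parallel_tol_deg: float = 5.0
    hough_pad_px: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.min_box_px < self.max_box_px):
            raise ValueError("require 0 < min_box_px < max_box_px")
        if not (0.0 <= self.border_mask_fraction < 0.5):
            raise ValueError("border_mask_fraction must lie in [0, 0.5)")
        if self.max_filter_size % 2 != 1:
            raise ValueError("max_filter_size must be odd")


@dataclass
class DualViewParams:
    min_aspect: float = 0.75
    midline_edge_count: int = 100
    neighbor_margin: int = 10
    neighbor_slack: int = 10
    canny_low: float = 50.0
    canny_high: float = 150.0
    canny_sigma: float = 1.0
    green_veto_fraction: float = 0.001

    def __post_init__(self) -> None:
        if min(self.min_aspect, self.midline_edge_count, self.neighbor_margin,
               self.neighbor_slack) <= 0:
            raise ValueError("all dual-view parameters must be positive")


def _enhanced_binary(scan: ScanImage, params: CaliperParams) -> np.ndarray:
    """Border-masked, edge-filtered, max-filtered, thresholded frame."""
    gray = to_grayscale(scan).pixels.copy()
    h, w = gray.shape
    bh = int(round(params.border_mask_fraction * h))
    bw = int(round(params.border_mask_fraction * w))
    if bh:
        gray[:bh, :] = 0
        gray[h - bh:, :] = 0
    if bw:
        gray[:, :bw] = 0
        gray[:, w - bw:] = 0
    im = Image.fromarray(gray)
    im = im.filter(ImageFilter.FIND_EDGES)
    if params.max_filter_size > 1:
        im = im.filter(ImageFilter.MaxFilter(params.max_filter_size))
    edges = np.asarray(im)
    binary = edges >= params.binarize_threshold
    # The border masking itself creates a step edge along the mask boundary;
    # erase that artifact band (boundary response spread by the max filter).
    pad = params.max_filter_size // 2 + 2
    if bh or bw:
        binary[:bh + pad, :] = False
        binary[h - bh - pad:, :] = False
        binary[:, :bw + pad] = False
        binary[:, w - bw - pad:] = False
    return binary


def detect_calipers(scan: ScanImage, params: Optional[CaliperParams] = None) -> list[BoundingBox]:
    """Bounding boxes of caliper-sized marks, in full-image coordinates."""
    params = params or CaliperParams()
    binary = _enhanced_binary(scan, params)
    if params.dilation_radius > 0 and binary.any():
        binary = dilation(binary, disk(params.dilation_radius))
    boxes: list[BoundingBox] = []
    labels = measure.label(binary, connectivity=2)
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox  # half-open, matching BoundingBox
        bh, bw = r1 - r0, c1 - c0
        if (params.min_box_px <= bh <= params.max_box_px
                and params.min_box_px <= bw <= params.max_box_px):
            boxes.append(BoundingBox(c0, r0, c1, r1))
    return boxes


def _segment_angle_deg(seg: tuple[tuple[int, int], tuple[int, int]]) -> float:
    (x0, y0), (x1, y1) = seg
    return float(np.degrees(np.arctan2(y1 - y0, x1 - x0))) % 180.0


def _line_intersection(
    a: tuple[tuple[int, int], tuple[int, int]],
    b: tuple[tuple[int, int], tuple[int, int]],
) -> Optional[tuple[float, float]]:
    (x1, y1), (x2, y2) = a
    (x3, y3), (x4, y4) = b
    denom = (x1 - x2) * (y3 - y4) - (y1 - y2) * (x3 - x4)
    if abs(denom) < 1e-12:
        return None
    px = ((x1 * y2 - y1 * x2) * (x3 - x4) - (x1 - x2) * (x3 * y4 - y3 * x4)) / denom
    py = ((x1 * y2 - y1 * x2) * (y3 - y4) - (y1 - y2) * (x3 * y4 - y3 * x4)) / denom
    return px, py


def _within_extent(pt, seg, pad: float) -> bool:
    (x0, y0), (x1, y1) = seg
    return (min(x0, x1) - pad <= pt[0] <= max(x0, x1) + pad
            and min(y0, y1) - pad <= pt[1] <= max(y0, y1) + pad)


def detect_calipers_hough(scan: ScanImage, params: Optional[CaliperParams] = None) -> bool:
    """True when two non-parallel detected line segments intersect.

    Runs probabilistic Hough line detection on the same enhanced binary image
    as the base method (the line gap bridges dotted annotation lines) and
    requires the supporting-line intersection point to fall inside both
    segments' bounding extents, padded by a few pixels.
    """
    params = params or CaliperParams()
    binary = _enhanced_binary(scan, params)
    if not binary.any():
        return False
    segments = probabilistic_hough_line(
        binary,
        threshold=params.hough_threshold,
        line_length=params.hough_min_line_px,
        line_gap=params.hough_line_gap_px,
        rng=0,
    )
    angles = [_segment_angle_deg(s) for s in segments]
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            diff = abs(angles[i] - angles[j])
            diff = min(diff, 180.0 - diff)
            if diff <= params.hough_parallel_tol_deg:
                continue
            pt = _line_intersection(segments[i], segments[j])
            if pt is None:
                continue
            if (_within_extent(pt, segments[i], params.hough_pad_px)
                    and _within_extent(pt, segments[j], params.hough_pad_px)):
                return True
    return False


def detect_dual_view(
    scan: ScanImage,
    params: Optional[DualViewParams] = None,
    masks: Optional[Sequence[ColorMaskSpec]] = None,
) -> bool:
    """Detect side-by-side composite frames by their midline edge column."""
    params = params or DualViewParams()
    if scan.width < 2 * params.neighbor_margin + 1:
        raise ValueError("image too narrow for the midline neighbor test")
    # Step 1: teal/green veto (elastography overlays are not dual views).
    if scan.channels == 3:
        if masks is None:
            masks = [default_mask_specs()["GREEN"]]
        veto = np.zeros((scan.height, scan.width), dtype=bool)
        for spec in masks:
            veto |= build_color_mask(scan, spec)
        if veto.mean() > params.green_veto_fraction:
            return False
    # Step 2: aspect-ratio veto.
    if scan.width < params.min_aspect * scan.height:
        return False
    # Steps 3-4: Canny edges, midline column test.
    gray = to_grayscale(scan).pixels.astype(float)
    edges = canny(
        gray,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low,
        high_threshold=params.canny_high,
    )
    col_counts = edges.sum(axis=0)
    m = scan.width // 2
    c_mid = int(col_counts[m])
    return (
        c_mid > params.midline_edge_count
        and c_mid > params.neighbor_slack + int(col_counts[m - params.neighbor_margin])
        and c_mid > params.neighbor_slack + int(col_counts[m + params.neighbor_margin])
    )
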