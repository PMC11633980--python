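"""Synthetic BUS-style screenshot generator with machine-readable labels.

Clinical ultrasound screenshots cannot ship with a test suite, so every
detector in this package is exercised against rendered phantoms instead: a
black frame, a speckle-textured scan area (rectangular, trapezoidal, convex
fan, or irregular/shadowed), and optional burnt-in artifacts - measurement
calipers, dotted spanning lines, scattered Doppler color, green indicator
graphics, side-by-side dual views, annotation text, or near-black invalid
frames.  Each phantom comes with a :class:`GroundTruth` record of exactly
what was drawn and where.

The speckle model is a clipped, spatially smoothed Gaussian field (default
mean 90, sd 30, correlation length ~1.5 px).  That is crude - no
point-spread function, no attenuation - but it reproduces the two properties
the detectors rely on: a bright, textured area on a black background, and
local gradients small compared to the burnt-in graphics.  Rendering is
bit-exact for a fixed seed.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw, ImageFont
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .image_model import BoundingBox, ScanImage, save_png

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomSpecError",
    "render_phantom",
    "generate_suite",
    "iter_suite_phantoms",
    "SUITE_CLASSES",
    "MANIFEST_COLUMNS",
]

SHAPES = ("RECTANGULAR", "TRAPEZOID", "CONVEX", "IRREGULAR")
CALIPER_STYLES = ("CROSS", "X", "NUMBER")

# Doppler palette: chromatically saturated but luma-matched to the speckle
# mean, as real overlays are drawn over (not brighter than) tissue.
DOPPLER_PALETTES = {
    "red": [(170, 40, 40), (200, 60, 50)],
    "blue": [(40, 40, 170), (50, 70, 200)],
}
INDICATOR_GREEN = (0, 220, 0)


class PhantomSpecError(ValueError):
    """A phantom spec violates one of its invariants."""


@dataclass
class PhantomSpec:
    canvas: tuple[int, int] = (400, 600)  # (height, width)
    shape: str = "RECTANGULAR"
    shape_geometry: Optional[dict] = None
    speckle: tuple[float, float] = (90.0, 30.0)  # (mean, sd)
    calipers: list[tuple[int, int, str, int]] = dc_field(default_factory=list)
    spanning_line: Optional[dict] = None  # {"p0": (x,y), "p1": (x,y), "dash": 4, "gap": 3}
    doppler_box: Optional[dict] = None  # {"box": (l,t,r,b), "palette": "red", "fraction": f}
    indicator_box: Optional[dict] = None  # {"box": (l,t,r,b), "kind": complete|partial|line}
    text_items: list[tuple[str, tuple[int, int], int]] = dc_field(default_factory=list)
    expected_fields: Optional[dict] = None
    dual_view: bool = False
    invalid: bool = False
    seed: int = 0

    def validate(self) -> None:
        h, w = self.canvas
        if h < 32 or w < 32:
            raise PhantomSpecError("canvas: too small to render a scan area")
        if self.shape not in SHAPES:
            raise PhantomSpecError(f"shape: unknown shape {self.shape!r}")
        if self.invalid and (
            self.calipers or self.spanning_line or self.doppler_box
            or self.indicator_box or self.text_items or self.dual_view
        ):
            raise PhantomSpecError("invalid: an invalid frame excludes all other artifacts")
        for cx, cy, style, size in self.calipers:
            if style not in CALIPER_STYLES:
                raise PhantomSpecError(f"calipers: unknown style {style!r}")
            if not (4 <= size <= 100):
                raise PhantomSpecError("calipers: size must lie in [4, 100] px")
            half = size // 2
            if not (half <= cx < w - half and half <= cy < h - half):
                raise PhantomSpecError("calipers: caliper extends beyond the canvas")
        for _, (tx, ty), _ in self.text_items:
            if not (0 <= tx < w and 0 <= ty < h):
                raise PhantomSpecError("text_items: anchor outside the canvas")


@dataclass
class GroundTruth:
    invalid: bool = False
    non_b_mode: bool = False
    dual_view: bool = False
    has_calipers: bool = False
    has_spanning_line: bool = False
    caliper_boxes: list[BoundingBox] = dc_field(default_factory=list)
    scan_area: Optional[BoundingBox] = None
    shape: str = "RECTANGULAR"
    strings: list[str] = dc_field(default_factory=list)
    fields: dict = dc_field(default_factory=dict)
    text_present: bool = False


def _speckle(rng: np.random.Generator, shape: tuple[int, int],
             mean: float, sd: float) -> np.ndarray:
    """Spatially correlated speckle field, clipped to [0, 255]."""
    noise = rng.standard_normal(shape)
    noise = gaussian_filter(noise, sigma=3.0)
    std = noise.std()
    if std > 0:
        noise *= sd / std
    return np.clip(np.round(mean + noise), 0, 255).astype(np.uint8)


def _default_geometry(shape: str, h: int, w: int, rng: np.random.Generator) -> dict:
    mx = int(0.08 * w)
    y0 = int(0.08 * h)
    y1 = h - int(0.10 * h)
    if shape == "TRAPEZOID":
        top_frac = 0.5 + 0.1 * rng.random()
        return {"x0": mx, "x1": w - mx, "y0": y0, "y1": y1, "top_frac": float(top_frac)}
    if shape == "CONVEX":
        half_angle = np.radians(30.0 + 8.0 * rng.random())
        return {"cx": w // 2, "apex_y": y0 - int(0.12 * h), "r0": int(0.10 * h),
                "r1": y1 - (y0 - int(0.12 * h)), "half_angle": float(half_angle)}
    if shape == "IRREGULAR":
        return {"x0": mx, "x1": w - mx, "y0": y0, "y1": y1,
                "amp": int(0.16 * h), "smooth": 25.0}
    return {"x0": mx, "x1": w - mx, "y0": y0, "y1": y1}


def _shape_mask(shape: str, geom: dict, h: int, w: int,
                rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    if shape == "RECTANGULAR":
        return ((xx >= geom["x0"]) & (xx < geom["x1"])
                & (yy >= geom["y0"]) & (yy < geom["y1"]))
    if shape == "TRAPEZOID":
        x0, x1, y0, y1 = geom["x0"], geom["x1"], geom["y0"], geom["y1"]
        cx = (x0 + x1) / 2.0
        full = (x1 - x0) / 2.0
        t = np.clip((yy - y0) / max(1, y1 - 1 - y0), 0.0, 1.0)
        half = full * (geom["top_frac"] + (1.0 - geom["top_frac"]) * t)
        return (yy >= y0) & (yy < y1) & (np.abs(xx - cx + 0.0) <= half)
    if shape == "CONVEX":
        dx = xx - geom["cx"]
        dy = yy - geom["apex_y"]
        r = np.hypot(dx, dy)
        ang = np.arctan2(dx, dy)  # 0 = straight down
        return ((r >= geom["r0"]) & (r <= geom["r1"])
                & (np.abs(ang) <= geom["half_angle"]) & (dy > 0))
    if shape == "IRREGULAR":
        x0, x1, y0, y1 = geom["x0"], geom["x1"], geom["y0"], geom["y1"]
        curve = gaussian_filter1d(rng.standard_normal(w), sigma=geom["smooth"])
        span = curve.max() - curve.min()
        if span > 0:
            curve = (curve - curve.min()) / span
        bottom = y1 - np.round(geom["amp"] * curve).astype(int)
        return (xx >= x0) & (xx < x1) & (yy >= y0) & (yy < bottom[None, :])
    raise PhantomSpecError(f"shape: unknown shape {shape!r}")


def _tight_bbox(mask: np.ndarray) -> BoundingBox:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return BoundingBox(int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)


def _draw_cross(gray: np.ndarray, cx: int, cy: int, size: int, value: int = 255) -> None:
    half = size // 2
    t = 1  # half-thickness -> 3 px arms
    gray[cy - half:cy + half + 1, cx - t:cx + t + 1] = value
    gray[cy - t:cy + t + 1, cx - half:cx + half + 1] = value


def _draw_x(gray: np.ndarray, cx: int, cy: int, size: int, value: int = 255) -> None:
    half = size // 2
    for d in range(-half, half + 1):
        for off in (-1, 0, 1):
            y1, x1 = cy + d, cx + d + off
            y2, x2 = cy + d, cx - d + off
            if 0 <= y1 < gray.shape[0] and 0 <= x1 < gray.shape[1]:
                gray[y1, x1] = value
            if 0 <= y2 < gray.shape[0] and 0 <= x2 < gray.shape[1]:
                gray[y2, x2] = value


def _draw_number(gray: np.ndarray, cx: int, cy: int, size: int, digit: str,
                 value: int = 255) -> None:
    im = Image.fromarray(gray)
    draw = ImageDraw.Draw(im)
    font = _font(size)
    draw.text((cx, cy), digit, fill=value, font=font, anchor="mm")
    gray[:, :] = np.asarray(im)


def _font(size: int) -> ImageFont.ImageFont:
    try:
        return ImageFont.load_default(size=size)
    except TypeError:  # older Pillow: fixed-size bitmap font
        return ImageFont.load_default()


def _draw_dotted_line(gray: np.ndarray, p0: tuple[int, int], p1: tuple[int, int],
                      dash: int = 4, gap: int = 3, value: int = 255) -> None:
    x0, y0 = p0
    x1, y1 = p1
    length = float(np.hypot(x1 - x0, y1 - y0))
    n = max(1, int(round(length)))
    for i in range(n + 1):
        if (i % (dash + gap)) >= dash:
            continue
        x = int(round(x0 + (x1 - x0) * i / n))
        y = int(round(y0 + (y1 - y0) * i / n))
        gray[max(0, y - 1):y + 1, max(0, x - 1):x + 1] = value


def render_phantom(spec: PhantomSpec) -> tuple[ScanImage, GroundTruth]:
    """Render a phantom and its ground truth; bit-exact for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    mean, sd = spec.speckle
    gt = GroundTruth(shape=spec.shape)

    if spec.invalid:
        gray = np.zeros((h, w), dtype=np.uint8)
        # a small bright remnant, keeping >= 80% of pixels below value 5
        ph, pw = int(0.25 * h), int(0.35 * w)
        py, px = int(0.3 * h), int(0.3 * w)
        gray[py:py + ph, px:px + pw] = _speckle(rng, (ph, pw), 60.0, 20.0)
        gt.invalid = True
        return ScanImage(gray, source_id=f"phantom-{spec.seed}"), gt

    gray = np.zeros((h, w), dtype=np.uint8)
    if spec.dual_view:
        geom = spec.shape_geometry or _default_geometry("RECTANGULAR", h, w, rng)
        y0, y1 = geom["y0"], geom["y1"]
        x0, x1 = geom["x0"], geom["x1"]
        m = w // 2
        # two independent views separated by a 1-px black gap just right of
        # the midline, so the left view's boundary edge sits on column m
        gray[y0:y1, x0:m + 1] = _speckle(rng, (y1 - y0, m + 1 - x0), mean, sd)
        gray[y0:y1, m + 2:x1] = _speckle(rng, (y1 - y0, x1 - m - 2), mean, sd)
        gt.dual_view = True
        gt.scan_area = BoundingBox(x0, y0, x1, y1)
    else:
        geom = spec.shape_geometry or _default_geometry(spec.shape, h, w, rng)
        mask = _shape_mask(spec.shape, geom, h, w, rng)
        field = _speckle(rng, (h, w), mean, sd)
        gray[mask] = field[mask]
        gt.scan_area = _tight_bbox(mask)

    for cx, cy, style, size in spec.calipers:
        if style == "CROSS":
            _draw_cross(gray, cx, cy, size)
        elif style == "X":
            _draw_x(gray, cx, cy, size)
        else:
            _draw_number(gray, cx, cy, size, digit=str(1 + (cx + cy) % 9))
        half = size // 2
        gt.caliper_boxes.append(BoundingBox(cx - half, cy - half, cx + half + 1, cy + half + 1))
    gt.has_calipers = bool(spec.calipers)

    if spec.spanning_line:
        sl = spec.spanning_line
        _draw_dotted_line(gray, tuple(sl["p0"]), tuple(sl["p1"]),
                          dash=int(sl.get("dash", 4)), gap=int(sl.get("gap", 3)))
        gt.has_spanning_line = True

    if spec.text_items:
        im = Image.fromarray(gray)
        draw = ImageDraw.Draw(im)
        for text, (tx, ty), size in spec.text_items:
            draw.text((tx, ty), text, fill=255, font=_font(size))
            gt.strings.append(text)
        gray = np.asarray(im).copy()
        gt.text_present = True
    gt.fields = dict(spec.expected_fields or {})

    needs_color = spec.doppler_box is not None or spec.indicator_box is not None
    if not needs_color:
        return ScanImage(gray, source_id=f"phantom-{spec.seed}"), gt

    rgb = np.repeat(gray[..., None], 3, axis=2).copy()
    if spec.doppler_box is not None:
        db = spec.doppler_box
        l, t, r, b = db["box"]
        if not (0 <= l < r <= w and 0 <= t < b <= h):
            raise PhantomSpecError("doppler_box: box outside the canvas")
        palette = DOPPLER_PALETTES[db.get("palette", "red")]
        frac = float(db.get("fraction", 0.25))
        sel = rng.random((b - t, r - l)) < frac
        colors = np.array(palette, dtype=np.uint8)
        idx = rng.integers(0, len(colors), size=sel.shape)
        block = rgb[t:b, l:r]
        block[sel] = colors[idx[sel]]
        gt.non_b_mode = True
    if spec.indicator_box is not None:
        ib = spec.indicator_box
        l, t, r, b = ib["box"]
        if not (0 <= l < r <= w and 0 <= t < b <= h):
            raise PhantomSpecError("indicator_box: box outside the canvas")
        kind = ib.get("kind", "complete")
        g = np.array(INDICATOR_GREEN, dtype=np.uint8)
        th = 2
        if kind == "line":
            rgb[t:b, l:l + th] = g
        else:
            rgb[t:t + th, l:r] = g        # top
            rgb[t:b, l:l + th] = g        # left
            rgb[t:b, r - th:r] = g        # right
            if kind == "complete":
                rgb[b - th:b, l:r] = g    # bottom
        gt.non_b_mode = True
    return ScanImage(rgb, source_id=f"phantom-{spec.seed}"), gt


# --------------------------------------------------------------------------
# Stratified suite generation

SUITE_CLASSES = (
    "plain",
    "calipers",
    "calipers_dotted",
    "doppler",
    "indicator_box",
    "dual_view",
    "invalid",
    "text",
    "text_procedural",
)

MANIFEST_COLUMNS = [
    "filename", "source_id", "class", "shape", "invalid", "non_b_mode",
    "dual_view", "has_calipers", "n_calipers", "caliper_boxes",
    "has_spanning_line", "scan_x_left", "scan_y_top", "scan_x_right",
    "scan_y_bottom", "strings", "text_present", "laterality", "orientation",
    "clock_hour", "clock_minute", "distance_cm", "axilla", "measurements",
    "procedural", "seed",
]

_LATERALITIES = ("LEFT", "RIGHT")
_LAT_TOKENS = {"LEFT": ("LEFT", "LT"), "RIGHT": ("RIGHT", "RT")}
_ORIENTATIONS = ("RAD", "ARAD", "TRANS", "LONG", "SAG", "OBL")
_ORI_TOKENS = {
    "RAD": ("RAD",), "ARAD": ("ARAD", "ANTIRAD"), "TRANS": ("TRANS", "TRV"),
    "LONG": ("LONG",), "SAG": ("SAG",), "OBL": ("OBL",),
}
_PROCEDURAL_STRINGS = (
    "US GUIDED BIOPSY", "CLIP PLACED", "MARKER PLACED", "POST BX", "FNA", "COIL PLACED",
)


def _caliper_positions(rng: np.random.Generator, k: int, h: int, w: int,
                       size: int) -> list[tuple[int, int]]:
    """Well-separated positions inside the unmasked central region."""
    margin = 20
    y_lo, y_hi = int(0.15 * h) + margin, h - int(0.15 * h) - margin
    x_lo, x_hi = int(0.15 * w) + margin, w - int(0.15 * w) - margin
    positions: list[tuple[int, int]] = []
    attempts = 0
    while len(positions) < k and attempts < 500:
        attempts += 1
        cx = int(rng.integers(x_lo, x_hi))
        cy = int(rng.integers(y_lo, y_hi))
        if all(max(abs(cx - px), abs(cy - py)) > 2 * size + 12
               for px, py in positions):
            positions.append((cx, cy))
    return positions


def _make_text_fields(i: int) -> tuple[list[str], dict]:
    """Deterministic BI-RADS-style annotation strings plus expected fields."""
    lat = _LATERALITIES[i % 2]
    lat_tok = _LAT_TOKENS[lat][i % 2 == 0]
    fields: dict = {
        "laterality": lat, "orientation": "NONE", "clock_hour": None,
        "clock_minute": None, "distance_cm": None, "axilla": False,
        "measurements": [], "procedural": False,
    }
    if i % 4 == 3:  # axillary imaging
        strings = [f"{lat_tok} AXILLA"]
        fields["axilla"] = True
        return strings, fields
    ori = _ORIENTATIONS[i % len(_ORIENTATIONS)]
    ori_tok = _ORI_TOKENS[ori][i % len(_ORI_TOKENS[ori])]
    hour = 1 + (i * 5) % 12
    minute = (0, 15, 30, 45)[i % 4]
    dist = round(0.5 * (1 + i % 8), 1)
    dist_str = f"{dist:g}"
    strings = [f"{lat_tok} BREAST {hour}:{minute:02d} {ori_tok} {dist_str} CM FN"]
    fields.update({
        "orientation": ori, "clock_hour": hour, "clock_minute": minute,
        "distance_cm": dist,
    })
    if i % 3 == 0:  # a lesion-measurement annotation line
        a, b = round(0.4 + 0.1 * (i % 9), 1), round(0.6 + 0.1 * (i % 7), 1)
        strings.append(f"{a:g} X {b:g} CM")
        fields["measurements"] = [a, b]
    return strings, fields


def build_class_spec(cls: str, i: int, seed: int,
                     canvas: tuple[int, int] = (400, 600)) -> PhantomSpec:
    """Spec for the i-th phantom of a suite class (deterministic in seed)."""
    cls_tag = zlib.crc32(cls.encode()) % 9973  # stable across processes
    phantom_seed = (seed * 100003 + cls_tag * 131 + i * 7919) % (2**31 - 1)
    rng = np.random.default_rng(phantom_seed)
    h, w = canvas
    spec = PhantomSpec(canvas=canvas, seed=phantom_seed)
    if cls == "plain":
        spec.shape = SHAPES[i % len(SHAPES)]
    elif cls == "calipers":
        size = 18 + 2 * (i % 4)
        k = 2 + i % 3
        style = ("CROSS", "X", "CROSS", "NUMBER")[i % 4]
        spec.calipers = [(cx, cy, style, size)
                         for cx, cy in _caliper_positions(rng, k, h, w, size)]
    elif cls == "calipers_dotted":
        size = 20
        # two marker pairs joined by a dotted spanning line (case-study style)
        y_mid = h // 2 + int(rng.integers(-30, 30))
        x0 = int(0.15 * w) + 40
        x1 = w - int(0.15 * w) - 40
        tilt = int(rng.integers(-25, 25))
        spec.calipers = [(x0, y_mid - tilt, "CROSS", size), (x1, y_mid + tilt, "CROSS", size)]
        spec.spanning_line = {"p0": (x0, y_mid - tilt), "p1": (x1, y_mid + tilt),
                              "dash": 4, "gap": 3}
    elif cls == "doppler":
        bw, bh = 160, 120
        l = int(0.2 * w) + int(rng.integers(0, int(0.25 * w)))
        t = int(0.2 * h) + int(rng.integers(0, int(0.2 * h)))
        spec.doppler_box = {"box": (l, t, l + bw, t + bh),
                            "palette": ("red", "blue")[i % 2], "fraction": 0.25}
    elif cls == "indicator_box":
        kind = ("complete", "partial", "line")[i % 3]
        if kind == "line":
            x = int(0.2 * w) + int(rng.integers(0, int(0.5 * w)))
            t = int(0.06 * h)
            spec.indicator_box = {"box": (x, t, x + 2, t + int(0.86 * h)), "kind": kind}
        else:
            side = 90 + int(rng.integers(0, 50))
            l = int(0.2 * w) + int(rng.integers(0, int(0.3 * w)))
            t = int(0.15 * h) + int(rng.integers(0, int(0.2 * h)))
            spec.indicator_box = {"box": (l, t, l + side, t + side), "kind": kind}
    elif cls == "dual_view":
        spec.dual_view = True
    elif cls == "invalid":
        spec.invalid = True
    elif cls == "text":
        strings, fields = _make_text_fields(i)
        spec.text_items = [(s, (10, 4 + 15 * j), 13) for j, s in enumerate(strings)]
        spec.expected_fields = fields
    elif cls == "text_procedural":
        lat = _LATERALITIES[i % 2]
        proc = _PROCEDURAL_STRINGS[i % len(_PROCEDURAL_STRINGS)]
        strings = [f"{_LAT_TOKENS[lat][0]} BREAST", proc]
        spec.text_items = [(s, (10, 4 + 15 * j), 13) for j, s in enumerate(strings)]
        spec.expected_fields = {
            "laterality": lat, "orientation": "NONE", "clock_hour": None,
            "clock_minute": None, "distance_cm": None, "axilla": False,
            "measurements": [], "procedural": True,
        }
    else:
        raise ValueError(f"unknown suite class {cls!r}")
    return spec


def iter_suite_phantoms(n_per_class: int, seed: int,
                        canvas: tuple[int, int] = (400, 600)):
    """Yield (class, index, ScanImage, GroundTruth) over the stratified suite."""
    for cls in SUITE_CLASSES:
        for i in range(n_per_class):
            spec = build_class_spec(cls, i, seed, canvas)
            scan, gt = render_phantom(spec)
            scan.source_id = f"{cls}_{i:04d}"
            yield cls, i, scan, gt


def _manifest_row(cls: str, i: int, filename: str, scan: ScanImage,
                  gt: GroundTruth, spec_seed: int) -> dict:
    f = gt.fields
    return {
        "filename": filename,
        "source_id": scan.source_id,
        "class": cls,
        "shape": gt.shape,
        "invalid": gt.invalid,
        "non_b_mode": gt.non_b_mode,
        "dual_view": gt.dual_view,
        "has_calipers": gt.has_calipers,
        "n_calipers": len(gt.caliper_boxes),
        "caliper_boxes": json.dumps(
            [[b.x_left, b.y_top, b.x_right, b.y_bottom] for b in gt.caliper_boxes]),
        "has_spanning_line": gt.has_spanning_line,
        "scan_x_left": gt.scan_area.x_left if gt.scan_area else "",
        "scan_y_top": gt.scan_area.y_top if gt.scan_area else "",
        "scan_x_right": gt.scan_area.x_right if gt.scan_area else "",
        "scan_y_bottom": gt.scan_area.y_bottom if gt.scan_area else "",
        "strings": json.dumps(gt.strings),
        "text_present": gt.text_present,
        "laterality": f.get("laterality", "NONE"),
        "orientation": f.get("orientation", "NONE"),
        "clock_hour": f.get("clock_hour") if f.get("clock_hour") is not None else "",
        "clock_minute": f.get("clock_minute") if f.get("clock_minute") is not None else "",
        "distance_cm": f.get("distance_cm") if f.get("distance_cm") is not None else "",
        "axilla": f.get("axilla", False),
        "measurements": json.dumps(f.get("measurements", [])),
        "procedural": f.get("procedural", False),
        "seed": spec_seed,
    }


def generate_suite(n_per_class: int, seed: int, out_dir: str,
                   canvas: tuple[int, int] = (400, 600)) -> pd.DataFrame:
    """Render the stratified suite to PNGs plus a manifest CSV.

    Returns the manifest as a DataFrame; ``manifest.csv`` is written next to
    the images.  Two runs with the same seed produce identical output.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for cls, i, scan, gt in iter_suite_phantoms(n_per_class, seed, canvas):
        filename = f"{scan.source_id}.png"
        save_png(scan, os.path.join(out_dir, filename))
        spec_seed = build_class_spec(cls, i, seed, canvas).seed
        rows.append(_manifest_row(cls, i, filename, scan, gt, spec_seed))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
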