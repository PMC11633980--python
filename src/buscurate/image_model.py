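"""Core raster types, file I/O, and low-level pixel statistics.

Every stage of the curation pipeline consumes :class:`ScanImage`, an 8-bit
grayscale or 3-channel raster, and exchanges regions as :class:`BoundingBox`
values.  The coordinate convention is fixed once here: 0-based, origin at the
top-left pixel, and boxes half-open on the right and bottom, so a box covers
columns ``[x_left, x_right)`` and rows ``[y_top, y_bottom)``.  Widths and
heights are then plain differences with no off-by-one ambiguity.

Supported sources are DICOM (pixel data only), PNG and JPEG.  Frames whose
stored bit depth exceeds 8 are rescaled linearly to 0-255 because every
intensity threshold downstream is stated on 8-bit values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from PIL import Image

__all__ = [
    "ScanImage",
    "BoundingBox",
    "FormatError",
    "load_image",
    "iter_frames",
    "save_png",
    "to_grayscale",
    "is_grayscale",
    "mode_pixel_value",
]


class FormatError(ValueError):
    """Raised when a file parses but its pixel encoding is unsupported."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box, half-open on the right and bottom edges."""

    x_left: int
    y_top: int
    x_right: int
    y_bottom: int

    def __post_init__(self) -> None:
        if not (self.x_left < self.x_right and self.y_top < self.y_bottom):
            raise ValueError(
                f"degenerate box ({self.x_left},{self.y_top},"
                f"{self.x_right},{self.y_bottom})"
            )
        if self.x_left < 0 or self.y_top < 0:
            raise ValueError("box extends beyond the top-left image corner")

    @property
    def w(self) -> int:
        return self.x_right - self.x_left

    @property
    def h(self) -> int:
        return self.y_bottom - self.y_top

    @property
    def area(self) -> int:
        return self.w * self.h

    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices selecting the box from an array."""
        return slice(self.y_top, self.y_bottom), slice(self.x_left, self.x_right)

    def contains(self, other: "BoundingBox") -> bool:
        return (
            self.x_left <= other.x_left
            and self.y_top <= other.y_top
            and other.x_right <= self.x_right
            and other.y_bottom <= self.y_bottom
        )

    def clipped(self, height: int, width: int) -> "BoundingBox":
        return BoundingBox(
            max(0, self.x_left),
            max(0, self.y_top),
            min(width, self.x_right),
            min(height, self.y_bottom),
        )


@dataclass
class ScanImage:
    """An 8-bit scan raster (H x W grayscale or H x W x 3 color)."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D pixel array, got {arr.ndim}-D")
        if arr.ndim == 3 and arr.shape[2] != 3:
            raise ValueError(f"3-D pixel array must have 3 channels, got {arr.shape[2]}")
        if arr.size == 0:
            raise ValueError("empty pixel array")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    def full_box(self) -> BoundingBox:
        return BoundingBox(0, 0, self.width, self.height)


_DICOM_SUFFIXES = {".dcm", ".dicom", ".dic"}
_PIL_SUFFIXES = {".png", ".jpg", ".jpeg"}


def _rescale_to_uint8(frame: np.ndarray) -> np.ndarray:
    """Linear min-max rescale of a single frame to 0-255."""
    frame = frame.astype(np.float64)
    lo, hi = frame.min(), frame.max()
    if hi <= lo:
        return np.zeros(frame.shape, dtype=np.uint8)
    return np.round((frame - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def _dicom_frames(path: str) -> Iterator[np.ndarray]:
    import pydicom

    try:
        ds = pydicom.dcmread(path, force=False)
        arr = ds.pixel_array
    except Exception as exc:  # pragma: no cover - error text only
        raise IOError(f"unreadable DICOM file: {path}: {exc}") from exc

    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric.startswith("YBR"):
        from pydicom.pixels import convert_color_space

        arr = convert_color_space(arr, photometric, "RGB")
        photometric = "RGB"
    if photometric not in ("MONOCHROME1", "MONOCHROME2", "RGB"):
        raise FormatError(
            f"unsupported photometric interpretation {photometric!r} in {path}"
        )

    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames > 1:
        frames = [arr[i] for i in range(n_frames)]
    else:
        frames = [arr]

    for frame in frames:
        if frame.dtype != np.uint8 or frame.max(initial=0) > 255:
            frame = _rescale_to_uint8(frame)
        frame = frame.astype(np.uint8)
        if photometric == "MONOCHROME1":
            # invert so low values mean dark everywhere downstream
            frame = (255 - frame.astype(np.int16)).astype(np.uint8)
        yield frame


def iter_frames(path: str, format_hint: Optional[str] = None) -> Iterator[ScanImage]:
    """Yield one :class:`ScanImage` per frame stored at ``path``."""
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    suffix = os.path.splitext(path)[1].lower()
    hint = (format_hint or "").upper()
    if hint == "DICOM" or (not hint and suffix in _DICOM_SUFFIXES):
        for i, frame in enumerate(_dicom_frames(path)):
            yield ScanImage(frame, source_id=f"{path}#{i}" if i else path)
        return
    if hint in ("PNG", "JPEG") or suffix in _PIL_SUFFIXES:
        try:
            with Image.open(path) as im:
                if im.mode not in ("L", "RGB"):
                    im = im.convert("RGB" if im.mode not in ("1", "I", "I;16") else "L")
                arr = np.asarray(im)
        except IOError:
            raise
        except Exception as exc:
            raise IOError(f"unreadable image file: {path}: {exc}") from exc
        if arr.dtype != np.uint8:
            arr = _rescale_to_uint8(arr)
        yield ScanImage(arr, source_id=path)
        return
    # No usable hint: try DICOM first, then PIL.
    try:
        frames = list(_dicom_frames(path))
    except (IOError, FormatError, Exception):
        frames = []
    if frames:
        for i, frame in enumerate(frames):
            yield ScanImage(frame, source_id=f"{path}#{i}" if i else path)
        return
    yield from iter_frames(path, format_hint="PNG")


def load_image(path: str, format_hint: Optional[str] = None) -> ScanImage:
    """Load the first frame stored at ``path`` as a :class:`ScanImage`."""
    return next(iter_frames(path, format_hint=format_hint))


def save_png(scan: ScanImage, path: str) -> None:
    """Write the scan as an 8-bit PNG (grayscale or RGB)."""
    Image.fromarray(scan.pixels).save(path, format="PNG")


# ITU-R 601 luma weights; thresholds downstream assume this conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(scan: ScanImage) -> ScanImage:
    """Convert to a single luma channel; 1-channel input passes through."""
    if scan.channels == 1:
        return scan
    gray = np.round(scan.pixels.astype(np.float64) @ _LUMA)
    return ScanImage(np.clip(gray, 0, 255).astype(np.uint8), source_id=scan.source_id)


def is_grayscale(scan: ScanImage, tol: int = 0) -> bool:
    """True when the image carries no chromatic information beyond ``tol``.

    A 1-channel image is always grayscale; a 3-channel image is grayscale when
    no pixel's channel spread (max channel minus min channel) exceeds ``tol``.
    """
    if scan.channels == 1:
        return True
    px = scan.pixels.astype(np.int16)
    spread = px.max(axis=2) - px.min(axis=2)
    return bool(spread.max() <= tol)


def mode_pixel_value(scan: ScanImage, region: Optional[BoundingBox] = None) -> int:
    """Most frequent intensity; ties resolve to the lowest value.

    The scan must be single-channel (callers convert first).  ``region``
    restricts the histogram to a sub-box.
    """
    if scan.channels != 1:
        raise ValueError("mode_pixel_value requires a 1-channel scan")
    px = scan.pixels
    if region is not None:
        px = px[region.slices()]
        if px.size == 0:
            raise ValueError("empty region")
    counts = np.bincount(px.ravel(), minlength=256)
    return int(counts.argmax())  # argmax returns the first (lowest) maximum
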