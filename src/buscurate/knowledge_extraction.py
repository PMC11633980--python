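"""OCR-driven extraction of burnt-in BI-RADS labeling fields.

Sonographers burn exam-positioning text into the scan pixels.  The ACR
BI-RADS labeling guidance (Section IC) makes four of those fields
non-identifying and useful for dataset curation: laterality (left/right
breast), anatomic location in clock-face notation, transducer orientation,
and distance from the nipple in centimeters.  This module also flags three
further text categories: axillary imaging, lesion measurements, and
procedural imaging (biopsy, clip/marker/coil placement).

Extraction is two-staged: an OCR backend turns the image into strings, and a
regular-expression vocabulary turns strings into structured fields.  The
vocabulary lives in a single editable YAML file so new annotation dialects
or languages can be added without touching code.  The OCR backend is an
interface, not a dependency: an EasyOCR adapter is provided for real scans,
and a deterministic stub backend that replays ground-truth strings supports
testing the grammar in isolation.

A number-CM group is consumed by at most one field: groups carrying a
from-nipple marker ("3 CM FN") are distances, all others are measurements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from enum import Enum
from importlib import resources
from typing import Iterable, Optional, Protocol

import yaml

from .image_model import BoundingBox, ScanImage

__all__ = [
    "Laterality",
    "Orientation",
    "TextDetection",
    "ExtractedFields",
    "Vocabulary",
    "load_vocabulary",
    "OCRBackend",
    "StubOCRBackend",
    "EasyOCRBackend",
    "OCRBackendUnavailable",
    "extract_text",
    "match_laterality",
    "match_orientation",
    "match_clock_position",
    "match_distance",
    "match_axilla",
    "match_measurement",
    "match_procedural",
    "extract_fields",
]


class Laterality(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    NONE = "NONE"
    CONFLICT = "CONFLICT"


class Orientation(str, Enum):
    RAD = "RAD"
    ARAD = "ARAD"
    TRANS = "TRANS"
    LONG = "LONG"
    SAG = "SAG"
    OBL = "OBL"
    NONE = "NONE"


@dataclass(frozen=True)
class TextDetection:
    text: str
    box: Optional[BoundingBox] = None
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("detection text must be non-empty")


@dataclass
class ExtractedFields:
    laterality: Laterality = Laterality.NONE
    orientation: Orientation = Orientation.NONE
    clock_position: Optional[tuple[int, int]] = None
    distance_from_nipple_cm: Optional[float] = None
    axilla: bool = False
    measurements_cm: list[float] = dc_field(default_factory=list)
    procedural: bool = False
    text_present: bool = False
    matched_tokens: list[tuple[str, str]] = dc_field(default_factory=list)


class Vocabulary:
    """Compiled regex tables, one list per field."""

    def __init__(self, raw: dict[str, list[str]]):
        self.raw = raw
        self.compiled: dict[str, list[re.Pattern[str]]] = {
            key: [re.compile(p) for p in patterns] for key, patterns in raw.items()
        }

    def patterns(self, key: str) -> list[re.Pattern[str]]:
        return self.compiled.get(key, [])


_DEFAULT_VOCAB: Optional[Vocabulary] = None


def load_vocabulary(path: Optional[str] = None) -> Vocabulary:
    """Load a vocabulary YAML; with no path, the bundled default (cached)."""
    global _DEFAULT_VOCAB
    if path is None:
        if _DEFAULT_VOCAB is None:
            text = resources.files("buscurate").joinpath("vocab.yaml").read_text()
            _DEFAULT_VOCAB = Vocabulary(yaml.safe_load(text))
        return _DEFAULT_VOCAB
    with open(path) as fh:
        return Vocabulary(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# OCR backends


class OCRBackendUnavailable(RuntimeError):
    """The requested OCR engine is not importable in this environment."""


class OCRBackend(Protocol):
    def read(self, scan: ScanImage) -> list[TextDetection]: ...


class StubOCRBackend:
    """Deterministic backend replaying known ground-truth strings.

    Maps a scan's ``source_id`` to the strings rendered onto it, so field
    extraction can be tested with OCR taken out of the loop.  Unknown ids
    yield no detections.
    """

    def __init__(self, strings_by_id: Optional[dict[str, list[str]]] = None):
        self.strings_by_id = strings_by_id or {}

    def read(self, scan: ScanImage) -> list[TextDetection]:
        return [
            TextDetection(text=s, confidence=1.0)
            for s in self.strings_by_id.get(scan.source_id, [])
            if s.strip()
        ]


class EasyOCRBackend:
    """Adapter around the EasyOCR engine (optional dependency)."""

    def __init__(self, languages: Iterable[str] = ("en",)):
        try:
            import easyocr
        except ImportError as exc:
            raise OCRBackendUnavailable(
                "easyocr is not installed; install the 'ocr' extra or use "
                "the stub backend (--ocr-backend stub)"
            ) from exc
        self._reader = easyocr.Reader(list(languages), verbose=False)

    def read(self, scan: ScanImage) -> list[TextDetection]:
        results = self._reader.readtext(scan.pixels)
        detections = []
        for quad, text, conf in results:
            if not text.strip():
                continue
            xs = [int(p[0]) for p in quad]
            ys = [int(p[1]) for p in quad]
            box = BoundingBox(min(xs), min(ys), max(max(xs), min(xs) + 1),
                              max(max(ys), min(ys) + 1))
            detections.append(TextDetection(text=text, box=box, confidence=float(conf)))
        return detections


_WS = re.compile(r"\s+")


def extract_text(
    scan: ScanImage,
    backend: OCRBackend,
    min_confidence: float = 0.3,
) -> list[TextDetection]:
    """Run OCR, drop low-confidence hits, and normalise strings.

    Strings are uppercased and internal whitespace collapsed, the form the
    vocabulary patterns expect.
    """
    out = []
    for det in backend.read(scan):
        if det.confidence < min_confidence:
            continue
        text = _WS.sub(" ", det.text.upper()).strip()
        if text:
            out.append(TextDetection(text=text, box=det.box, confidence=det.confidence))
    return out


# --------------------------------------------------------------------------
# Field grammars (pure functions of an uppercased string)


def _first_match(text: str, patterns: list[re.Pattern[str]]) -> Optional[re.Match[str]]:
    for pat in patterns:
        m = pat.search(text)
        if m:
            return m
    return None


def match_laterality(text: str, vocab: Optional[Vocabulary] = None) -> Laterality:
    vocab = vocab or load_vocabulary()
    left = _first_match(text, vocab.patterns("laterality_left")) is not None
    right = _first_match(text, vocab.patterns("laterality_right")) is not None
    if left and right:
        return Laterality.CONFLICT
    if left:
        return Laterality.LEFT
    if right:
        return Laterality.RIGHT
    return Laterality.NONE


def match_orientation(text: str, vocab: Optional[Vocabulary] = None) -> Orientation:
    vocab = vocab or load_vocabulary()
    # ARAD aliases are tested before RAD so "ANTIRAD" never falls through.
    for label in (Orientation.ARAD, Orientation.RAD, Orientation.TRANS,
                  Orientation.LONG, Orientation.SAG, Orientation.OBL):
        if _first_match(text, vocab.patterns(f"orientation_{label.value}")):
            return label
    return Orientation.NONE


def match_clock_position(
    text: str, vocab: Optional[Vocabulary] = None
) -> Optional[tuple[int, int]]:
    vocab = vocab or load_vocabulary()
    m = _first_match(text, vocab.patterns("clock_position"))
    if m is None:
        return None
    hour = int(m.group(1))
    minute = int(m.group(2)) if m.lastindex and m.lastindex >= 2 and m.group(2) else 0
    if not (1 <= hour <= 12 and 0 <= minute <= 59):
        return None
    return hour, minute


def match_distance(text: str, vocab: Optional[Vocabulary] = None) -> Optional[float]:
    vocab = vocab or load_vocabulary()
    m = _first_match(text, vocab.patterns("distance_from_nipple"))
    if m is None:
        return None
    return float(m.group(1))


def match_axilla(text: str, vocab: Optional[Vocabulary] = None) -> bool:
    vocab = vocab or load_vocabulary()
    return _first_match(text, vocab.patterns("axilla")) is not None


def match_measurement(text: str, vocab: Optional[Vocabulary] = None) -> list[float]:
    vocab = vocab or load_vocabulary()
    values: list[float] = []
    for pat in vocab.patterns("measurement"):
        for m in pat.finditer(text):
            values.append(float(m.group(1)))
            if m.lastindex and m.lastindex >= 2 and m.group(2):
                values.append(float(m.group(2)))
    return values


def match_procedural(text: str, vocab: Optional[Vocabulary] = None) -> bool:
    vocab = vocab or load_vocabulary()
    return _first_match(text, vocab.patterns("procedural")) is not None


def extract_fields(
    detections: list[TextDetection],
    vocab: Optional[Vocabulary] = None,
) -> ExtractedFields:
    """Fold per-detection grammar matches into one structured record.

    Laterality becomes CONFLICT when both sides match anywhere across the
    detections (a review flag for mislabeled or dual-view scans); the first
    match wins for orientation, clock position and distance; axilla and
    procedural are any-match flags; measurements accumulate.
    """
    vocab = vocab or load_vocabulary()
    out = ExtractedFields(text_present=bool(detections))
    saw_left = saw_right = False
    for det in detections:
        text = det.text
        lat = match_laterality(text, vocab)
        if lat in (Laterality.LEFT, Laterality.CONFLICT):
            saw_left = True
        if lat in (Laterality.RIGHT, Laterality.CONFLICT):
            saw_right = True
        if lat is not Laterality.NONE:
            out.matched_tokens.append(("laterality", text))
        ori = match_orientation(text, vocab)
        if ori is not Orientation.NONE:
            if out.orientation is Orientation.NONE:
                out.orientation = ori
            out.matched_tokens.append(("orientation", text))
        clock = match_clock_position(text, vocab)
        if clock is not None:
            if out.clock_position is None:
                out.clock_position = clock
            out.matched_tokens.append(("clock_position", text))
        dist = match_distance(text, vocab)
        if dist is not None:
            if out.distance_from_nipple_cm is None:
                out.distance_from_nipple_cm = dist
            out.matched_tokens.append(("distance_from_nipple", text))
        if match_axilla(text, vocab):
            out.axilla = True
            out.matched_tokens.append(("axilla", text))
        meas = match_measurement(text, vocab)
        if meas:
            out.measurements_cm.extend(meas)
            out.matched_tokens.append(("measurement", text))
        if match_procedural(text, vocab):
            out.procedural = True
            out.matched_tokens.append(("procedural", text))
    if saw_left and saw_right:
        out.laterality = Laterality.CONFLICT
    elif saw_left:
        out.laterality = Laterality.LEFT
    elif saw_right:
        out.laterality = Laterality.RIGHT
    return out
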