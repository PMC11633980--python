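"""Batch orchestration of the curation stages.

Stages run in a fixed order per image: invalid check, scan-area crop, mode
classification (its flow-fraction denominator is the stage-1 crop box),
dual-view detection, caliper detection (optionally with the Hough
extension), then OCR field extraction.  Every stage can be disabled
independently; disabling one never changes another's verdict, with two
documented exceptions: an invalid frame short-circuits all later stages
(near-black frames make the downstream tests meaningless), and the crop box
feeds the mode classifier's denominator.

A stage failure (e.g. a degenerate crop on an unusual frame) is recorded on
the image's report row and the batch continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field as dc_field
from typing import Optional

import pandas as pd

from .artifact_detection import (CaliperParams, DualViewParams, detect_calipers,
                                 detect_calipers_hough, detect_dual_view)
from .image_model import BoundingBox, ScanImage, iter_frames, save_png
from .knowledge_extraction import (ExtractedFields, OCRBackend, Vocabulary,
                                   extract_fields, extract_text)
from .scan_cropping import CropParams, CropResult, DegenerateScanError, crop
from .scan_filtering import (ColorMaskSpec, FilterParams, ScanMode,
                             classify_scan_mode, default_mask_specs,
                             detect_invalid)

logger = logging.getLogger("buscurate")

__all__ = ["PipelineConfig", "ScanFlags", "process_image", "process_directory",
           "load_config", "ALL_STAGES", "REPORT_COLUMNS"]

ALL_STAGES = ("invalid", "crop", "mode", "dualview", "calipers", "ocr")


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = ALL_STAGES
    filter_params: FilterParams = dc_field(default_factory=FilterParams)
    caliper_params: CaliperParams = dc_field(default_factory=CaliperParams)
    dualview_params: DualViewParams = dc_field(default_factory=DualViewParams)
    crop_params: CropParams = dc_field(default_factory=CropParams)
    mask_specs: dict[str, ColorMaskSpec] = dc_field(default_factory=default_mask_specs)
    ocr_backend: Optional[OCRBackend] = None
    vocabulary: Optional["Vocabulary"] = None
    min_confidence: float = 0.3
    save_crops_dir: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class ScanFlags:
    source_id: str
    is_invalid: Optional[bool] = None
    is_non_b_mode: Optional[bool] = None
    is_dual_view: Optional[bool] = None
    has_calipers: Optional[bool] = None
    caliper_boxes: list[BoundingBox] = dc_field(default_factory=list)
    crop: Optional[CropResult] = None
    fields: Optional[ExtractedFields] = None
    errors: list[str] = dc_field(default_factory=list)

    def to_row(self) -> dict:
        f = self.fields
        c2 = self.crop.stage2_box if self.crop else None
        return {
            "source_id": self.source_id,
            "invalid": _tri(self.is_invalid),
            "non_b_mode": _tri(self.is_non_b_mode),
            "dual_view": _tri(self.is_dual_view),
            "has_calipers": _tri(self.has_calipers),
            "caliper_boxes": json.dumps(
                [[b.x_left, b.y_top, b.x_right, b.y_bottom] for b in self.caliper_boxes]),
            "shape_class": self.crop.shape_class.value if self.crop else "",
            "x_left": c2.x_left if c2 else "",
            "y_top": c2.y_top if c2 else "",
            "x_right": c2.x_right if c2 else "",
            "y_bottom": c2.y_bottom if c2 else "",
            "text_present": _tri(f.text_present if f else None),
            "laterality": f.laterality.value if f else "",
            "orientation": f.orientation.value if f else "",
            "clock_hour": f.clock_position[0] if f and f.clock_position else "",
            "clock_minute": f.clock_position[1] if f and f.clock_position else "",
            "distance_cm": f.distance_from_nipple_cm
            if f and f.distance_from_nipple_cm is not None else "",
            "axilla": _tri(f.axilla if f else None),
            "measurements": json.dumps(f.measurements_cm) if f else "",
            "procedural": _tri(f.procedural if f else None),
            "errors": ";".join(self.errors),
        }


def _tri(value: Optional[bool]) -> str:
    return "" if value is None else str(bool(value))


REPORT_COLUMNS = list(ScanFlags(source_id="x").to_row().keys())


def process_image(scan: ScanImage, config: Optional[PipelineConfig] = None) -> ScanFlags:
    """Run the enabled stages over one image."""
    config = config or PipelineConfig()
    stages = set(config.stages)
    flags = ScanFlags(source_id=scan.source_id)

    if "invalid" in stages:
        flags.is_invalid = detect_invalid(scan, config.filter_params)
        if flags.is_invalid:
            return flags  # short-circuit: later verdicts are meaningless

    scan_area: Optional[BoundingBox] = None
    if "crop" in stages:
        try:
            flags.crop = crop(scan, config.crop_params)
            scan_area = flags.crop.stage1_box
        except DegenerateScanError as exc:
            flags.errors.append(f"crop: {exc}")
            logger.warning("crop failed for %s: %s", scan.source_id, exc)

    if "mode" in stages:
        mode = classify_scan_mode(scan, config.filter_params, config.mask_specs,
                                  scan_area=scan_area)
        flags.is_non_b_mode = mode is ScanMode.NON_B_MODE

    if "dualview" in stages:
        try:
            flags.is_dual_view = detect_dual_view(scan, config.dualview_params)
        except ValueError as exc:
            flags.errors.append(f"dualview: {exc}")

    if "calipers" in stages:
        flags.caliper_boxes = detect_calipers(scan, config.caliper_params)
        flags.has_calipers = bool(flags.caliper_boxes)
        if config.caliper_params.hough_enabled and not flags.has_calipers:
            flags.has_calipers = detect_calipers_hough(scan, config.caliper_params)

    if "ocr" in stages and config.ocr_backend is not None:
        detections = extract_text(scan, config.ocr_backend,
                                  min_confidence=config.min_confidence)
        flags.fields = extract_fields(detections, vocab=config.vocabulary)

    return flags


def process_directory(
    in_dir: str,
    config: Optional[PipelineConfig] = None,
    report_path: Optional[str] = None,
) -> dict:
    """Process every readable image in ``in_dir`` (lexicographic order).

    Writes a CSV report (plus a JSON-lines mirror) when ``report_path`` is
    given and returns summary counts per flag.
    """
    config = config or PipelineConfig()
    names = sorted(
        n for n in os.listdir(in_dir)
        if os.path.splitext(n)[1].lower() in (".png", ".jpg", ".jpeg", ".dcm", ".dicom")
    )
    if not names:
        logger.warning("no images found in %s", in_dir)
    rows = []
    summary = {"images": 0, "failures": 0, "invalid": 0, "non_b_mode": 0,
               "dual_view": 0, "has_calipers": 0, "text_present": 0}
    for name in names:
        path = os.path.join(in_dir, name)
        try:
            scan = next(iter_frames(path))
        except Exception as exc:
            logger.error("unreadable image %s: %s", path, exc)
            failed = ScanFlags(source_id=os.path.splitext(name)[0])
            failed.errors.append(f"load: {exc}")
            rows.append(failed.to_row())
            summary["failures"] += 1
            summary["images"] += 1
            continue
        scan.source_id = os.path.splitext(name)[0]
        flags = process_image(scan, config)
        if config.save_crops_dir and flags.crop is not None:
            os.makedirs(config.save_crops_dir, exist_ok=True)
            box = flags.crop.stage2_box
            cropped = ScanImage(scan.pixels[box.slices()], source_id=scan.source_id)
            save_png(cropped, os.path.join(config.save_crops_dir, f"{scan.source_id}.png"))
        rows.append(flags.to_row())
        summary["images"] += 1
        for key in ("invalid", "non_b_mode", "dual_view", "has_calipers", "text_present"):
            if rows[-1][key] == "True":
                summary[key] += 1
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if report_path:
        report.to_csv(report_path, index=False)
        with open(os.path.splitext(report_path)[0] + ".jsonl", "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    summary["report"] = report
    return summary


def load_config(path: str) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Recognised blocks: ``stages`` (list), ``filtering``, ``calipers``,
    ``dualview``, ``crop`` (flat key-value maps onto the matching params
    dataclass), and ``filtering.masks.<NAME>.{hsv_low,hsv_high,dilation_radius}``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    def build(cls, block: dict):
        valid = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in (block or {}).items() if k in valid})

    filtering = dict(raw.get("filtering") or {})
    mask_block = filtering.pop("masks", {}) or {}
    specs = default_mask_specs()
    for name, m in mask_block.items():
        base = specs.get(name)
        specs[name] = ColorMaskSpec(
            name=name,
            hsv_low=tuple(m.get("hsv_low", base.hsv_low if base else (0, 0, 0))),
            hsv_high=tuple(m.get("hsv_high", base.hsv_high if base else (179, 255, 255))),
            dilation_radius=int(m.get("dilation_radius",
                                      base.dilation_radius if base else 2)),
            extra_low=base.extra_low if base else None,
            extra_high=base.extra_high if base else None,
        )
    return PipelineConfig(
        stages=tuple(raw.get("stages", ALL_STAGES)),
        filter_params=build(FilterParams, filtering),
        caliper_params=build(CaliperParams, raw.get("calipers")),
        dualview_params=build(DualViewParams, raw.get("dualview")),
        crop_params=build(CropParams, raw.get("crop")),
        mask_specs=specs,
    )
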