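"""Per-task scoring of pipeline predictions against labels.

Every curation decision is a binary classification (invalid / not invalid,
calipers / no calipers, ...), scored by sensitivity, specificity and F1 from
a confusion matrix.  Text-field tasks are stricter: a prediction counts as a
true positive only when the field is both recognised *and* its value matches
the label exactly - recognising "some text" where "3:00" was rendered is not
a hit.

Reported metrics are rounded half-away-from-zero to 3 decimals; raw values
stay available on the returned objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "sensitivity",
    "specificity",
    "f1",
    "round3",
    "score_binary",
    "score_manifest",
    "TEXT_FIELD_TASKS",
    "FLAG_TASKS",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions: Sequence[bool], labels: Sequence[bool]) -> ConfusionMatrix:
    if len(predictions) != len(labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(labels)} labels")
    tp = fp = tn = fn = 0
    for p, y in zip(predictions, labels):
        if y:
            tp += bool(p)
            fn += not p
        else:
            fp += bool(p)
            tn += not p
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity(cm: ConfusionMatrix) -> Optional[float]:
    """tp / (tp + fn); None when there are no positives."""
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else None


def specificity(cm: ConfusionMatrix) -> Optional[float]:
    """tn / (tn + fp); None when there are no negatives."""
    denom = cm.tn + cm.fp
    return cm.tn / denom if denom else None


def f1(cm: ConfusionMatrix) -> Optional[float]:
    """2 tp / (2 tp + fp + fn); None when the denominator vanishes."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    return 2 * cm.tp / denom if denom else None


def round3(value: Optional[float]) -> Optional[float]:
    """Round half away from zero at 3 decimals (table convention)."""
    if value is None:
        return None
    return float(Decimal(repr(value)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def score_binary(predictions: Sequence[bool], labels: Sequence[bool]) -> dict:
    cm = confusion(predictions, labels)
    return {
        "cm": cm,
        "sensitivity": sensitivity(cm),
        "specificity": specificity(cm),
        "f1": f1(cm),
    }


# Flag tasks compare booleans; text-field tasks compare recognised values.
FLAG_TASKS = ("invalid", "non_b_mode", "dual_view", "has_calipers",
              "text_present", "axilla", "procedural")
TEXT_FIELD_TASKS = ("laterality", "orientation", "position", "distance", "measurement")


def _norm(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = str(value).strip()
    return "" if s.lower() in ("", "nan", "none") else s


def _field_state(row: pd.Series, task: str, prefix: str) -> tuple[bool, str]:
    """(present, canonical value) of a text-field task in a joined row."""
    if task == "laterality":
        v = _norm(row.get(f"laterality{prefix}")).upper()
        return v not in ("", "NONE"), v
    if task == "orientation":
        v = _norm(row.get(f"orientation{prefix}")).upper()
        return v not in ("", "NONE"), v
    if task == "position":
        hr = _norm(row.get(f"clock_hour{prefix}"))
        mn = _norm(row.get(f"clock_minute{prefix}"))
        if not hr:
            return False, ""
        minute = int(float(mn)) if mn else 0
        return True, f"{int(float(hr))}:{minute:02d}"
    if task == "distance":
        v = _norm(row.get(f"distance_cm{prefix}"))
        return (True, f"{float(v):g}") if v else (False, "")
    if task == "measurement":
        v = _norm(row.get(f"measurements{prefix}"))
        try:
            values = sorted(float(x) for x in json.loads(v)) if v else []
        except (ValueError, TypeError):
            values = []
        return bool(values), json.dumps(values)
    raise ValueError(f"unknown text-field task {task!r}")


def evaluate_synthetic_suite(n_per_class: int, seed: int) -> dict[str, dict]:
    """Run every detector over the stratified phantom suite and score it.

    Returns ``{task: {"cm": ConfusionMatrix, "sensitivity": ..., ...}}`` for
    the invalid, non-B-mode, dual-view and caliper tasks, each scored against
    generator ground truth.  Caliper sensitivity is measured on the
    plain-cross caliper class and caliper specificity on caliper-free B-mode
    phantoms: caliper cleaning applies to the B-mode population, which has
    already passed the mode filter (dotted-line phantoms are the Hough
    extension's target and are scored separately).
    """
    from .artifact_detection import detect_calipers, detect_dual_view
    from .scan_filtering import ScanMode, classify_scan_mode, detect_invalid
    from .synthetic_fixtures import iter_suite_phantoms

    caliper_negative_classes = {"plain", "text", "text_procedural", "dual_view", "invalid"}
    preds: dict[str, list[bool]] = {t: [] for t in
                                    ("invalid", "non_b_mode", "dual_view", "calipers")}
    labels: dict[str, list[bool]] = {t: [] for t in preds}
    for cls, _, scan, gt in iter_suite_phantoms(n_per_class, seed):
        preds["invalid"].append(detect_invalid(scan))
        labels["invalid"].append(gt.invalid)
        preds["non_b_mode"].append(classify_scan_mode(scan) is ScanMode.NON_B_MODE)
        labels["non_b_mode"].append(gt.non_b_mode)
        preds["dual_view"].append(detect_dual_view(scan))
        labels["dual_view"].append(gt.dual_view)
        if cls == "calipers" or cls in caliper_negative_classes:
            preds["calipers"].append(bool(detect_calipers(scan)))
            labels["calipers"].append(gt.has_calipers)
    return {task: score_binary(preds[task], labels[task]) for task in preds}


def evaluate_caliper_case_study(n: int, seed: int) -> dict[str, dict]:
    """Base vs Hough-extended caliper detection on dotted-line phantoms.

    Renders ``n`` dotted-spanning-line caliper phantoms (positives) and ``n``
    rectangular caliper-free phantoms (negatives, matching the case-study
    dataset's rectangular scan areas) and scores both detectors.
    """
    from .artifact_detection import detect_calipers, detect_calipers_hough
    from .synthetic_fixtures import build_class_spec, render_phantom

    base_p, hough_p, labels = [], [], []
    for i in range(n):
        scan, _ = render_phantom(build_class_spec("calipers_dotted", i, seed))
        base_p.append(bool(detect_calipers(scan)))
        hough_p.append(bool(detect_calipers(scan)) or detect_calipers_hough(scan))
        labels.append(True)
    for i in range(n):
        scan, _ = render_phantom(build_class_spec("plain", 4 * i, seed))  # rectangular
        base_p.append(bool(detect_calipers(scan)))
        hough_p.append(bool(detect_calipers(scan)) or detect_calipers_hough(scan))
        labels.append(False)
    return {"base": score_binary(base_p, labels),
            "hough": score_binary(hough_p, labels)}


def score_manifest(
    predictions_csv: str,
    manifest_csv: str,
    tasks: Sequence[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Join predictions to labels on source_id and score each task.

    Returns (score table, warnings).  Unmatched ids on either side are
    reported as warnings and excluded from the counts.
    """
    preds = pd.read_csv(predictions_csv, dtype=str)
    labels = pd.read_csv(manifest_csv, dtype=str)
    merged = preds.merge(labels, on="source_id", how="inner",
                         suffixes=("_pred", "_true"))
    warnings = []
    missing_pred = set(labels["source_id"]) - set(preds["source_id"])
    missing_true = set(preds["source_id"]) - set(labels["source_id"])
    if missing_pred:
        warnings.append(f"{len(missing_pred)} labeled ids without predictions")
    if missing_true:
        warnings.append(f"{len(missing_true)} predicted ids without labels")

    def as_bool(series: pd.Series) -> list[bool]:
        return [str(v).strip().lower() in ("true", "1", "yes") for v in series]

    rows = []
    for task in tasks:
        if task in FLAG_TASKS:
            p = as_bool(merged.get(f"{task}_pred", merged.get(task, pd.Series(dtype=str))))
            y = as_bool(merged.get(f"{task}_true", merged.get(task, pd.Series(dtype=str))))
            cm = confusion(p, y)
        elif task in TEXT_FIELD_TASKS:
            tp = fp = tn = fn = 0
            for _, row in merged.iterrows():
                p_present, p_val = _field_state(row, task, "_pred")
                y_present, y_val = _field_state(row, task, "_true")
                if y_present:
                    # footnote semantics: TP only on an exact value match
                    if p_present and p_val == y_val:
                        tp += 1
                    else:
                        fn += 1
                else:
                    if p_present:
                        fp += 1
                    else:
                        tn += 1
            cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        else:
            raise ValueError(f"unknown task {task!r}")
        rows.append({
            "task": task, "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
            "sensitivity": round3(sensitivity(cm)),
            "specificity": round3(specificity(cm)),
            "f1": round3(f1(cm)),
        })
    return pd.DataFrame(rows), warnings
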