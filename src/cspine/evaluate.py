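"""Detection metrics (accuracy, precision, recall, AP/mAP) and distance
agreement (Pearson correlation) between two sets of measurements.

Accuracy follows the four-count definition ``(Tp+Tn)/(Tp+Fp+Tn+Fn)``; in the
detection setting true negatives are ill-defined and fixed at 0, so reported
accuracy reduces to ``Tp/(Tp+Fp+Fn)``. AP uses all-points interpolation of
the precision-recall staircase; mAP averages the per-class APs at a single
IoU threshold (0.5 by default, i.e. mAP50).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detection import Detection
from .measure import MeasurementReport

BoxT = tuple[float, float, float, float]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class PRCurve:
    """(recall, precision) points ordered by descending confidence, plus AP."""

    points: list[tuple[float, float]] = field(default_factory=list)
    ap: float | None = None


def iou(a: BoxT, b: BoxT) -> float:
    """Intersection-over-union of two half-open boxes."""
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0.0, ix1 - ix0) * max(0.0, iy1 - iy0)
    if inter == 0.0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def _greedy_match(
    predictions: Sequence[Detection],
    truths: Sequence[tuple[str, BoxT]],
    iou_threshold: float,
) -> list[tuple[Detection, bool]]:
    """Greedy matching by descending confidence; returns (pred, is_tp) pairs
    in the matching order."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    order = sorted(range(len(predictions)), key=lambda i: -predictions[i].confidence)
    matched = [False] * len(truths)
    out: list[tuple[Detection, bool]] = []
    for i in order:
        pred = predictions[i]
        best_j, best_iou = -1, 0.0
        for j, (lab, box) in enumerate(truths):
            if matched[j] or lab != pred.label:
                continue
            v = iou(pred.box, box)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[best_j] = True
            out.append((pred, True))
        else:
            out.append((pred, False))
    return out


def match_detections(
    predictions: Sequence[Detection],
    truths: Sequence[tuple[str, BoxT]],
    iou_threshold: float = 0.5,
) -> dict[str, ConfusionCounts]:
    """Per-class confusion counts from greedy IoU matching.

    A prediction is a true positive iff its label matches an as-yet-unmatched
    truth with IoU >= threshold; leftover predictions are false positives and
    leftover truths false negatives. Tn is 0 by construction.
    """
    scored = _greedy_match(predictions, truths, iou_threshold)
    classes = {p.label for p in predictions} | {lab for lab, _ in truths}
    counts = {c: ConfusionCounts() for c in classes}
    for pred, is_tp in scored:
        if is_tp:
            counts[pred.label].tp += 1
        else:
            counts[pred.label].fp += 1
    for c in classes:
        n_truth = sum(1 for lab, _ in truths if lab == c)
        counts[c].fn = n_truth - counts[c].tp
    return counts


def scored_matches(
    predictions: Sequence[Detection],
    truths: Sequence[tuple[str, BoxT]],
    iou_threshold: float = 0.5,
) -> dict[str, tuple[list[tuple[float, bool]], int]]:
    """Per-class ``([(confidence, is_tp), ...], n_truth)`` for AP computation."""
    scored = _greedy_match(predictions, truths, iou_threshold)
    classes = {p.label for p in predictions} | {lab for lab, _ in truths}
    out: dict[str, tuple[list[tuple[float, bool]], int]] = {}
    for c in classes:
        per_class = [(p.confidence, tp) for p, tp in scored if p.label == c]
        n_truth = sum(1 for lab, _ in truths if lab == c)
        out[c] = (per_class, n_truth)
    return out


def rates(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(accuracy, precision, recall); ``None`` where the denominator is zero."""
    total = c.tp + c.fp + c.tn + c.fn
    accuracy = (c.tp + c.tn) / total if total > 0 else None
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    return accuracy, precision, recall


def average_precision(
    scored: Sequence[tuple[float, bool]], n_truth: int
) -> PRCurve:
    """All-points-interpolated average precision.

    ``scored`` holds (confidence, is_tp) per prediction; AP is the area under
    the precision envelope of the recall staircase,
    ``sum (r_i - r_{i-1}) * max_{k>=i} p_k``.
    """
    if n_truth < 1:
        return PRCurve(points=[], ap=None)
    order = sorted(range(len(scored)), key=lambda i: -scored[i][0])
    tp = fp = 0
    points: list[tuple[float, float]] = []
    for i in order:
        if scored[i][1]:
            tp += 1
        else:
            fp += 1
        points.append((tp / n_truth, tp / (tp + fp)))
    precisions = np.array([p for _, p in points], dtype=float)
    recalls = np.array([r for r, _ in points], dtype=float)
    if len(points) == 0:
        return PRCurve(points=[], ap=0.0)
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recalls, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return PRCurve(points=points, ap=float(ap))


def mean_ap(curves: Mapping[str, PRCurve] | Iterable[PRCurve]) -> float | None:
    """Mean of the defined per-class APs; ``None`` if none is defined."""
    if isinstance(curves, Mapping):
        curves = curves.values()
    aps = [c.ap for c in curves if c.ap is not None]
    return float(np.mean(aps)) if aps else None


def ppmcc(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson product-moment correlation; ``None`` for constant input."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if xa.size < 2:
        raise ValueError("need at least 2 paired values")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    denom = float(np.sqrt((xd * xd).sum() * (yd * yd).sum()))
    if denom == 0.0:
        return None
    return float((xd * yd).sum() / denom)


def _measurement_map(report: MeasurementReport) -> dict[tuple[str, str, str], float]:
    return {
        (m.kind, m.from_label, m.to_label): m.distance for m in report.measurements
    }


def agreement_report(
    system: MeasurementReport | Sequence[MeasurementReport],
    reference: MeasurementReport | Sequence[MeasurementReport],
) -> pd.DataFrame:
    """Per-case Pearson agreement between two sets of distance measurements.

    Cases are matched by ``image_id`` and measurements by (kind, level pair).
    Returns a table with one row per case plus an ``Average`` row and one
    column per measurement kind; a cell is NaN when fewer than two common
    pairs exist for that kind.
    """
    sys_reports = [system] if isinstance(system, MeasurementReport) else list(system)
    ref_reports = (
        [reference] if isinstance(reference, MeasurementReport) else list(reference)
    )
    refs = {r.image_id: r for r in ref_reports}
    kinds = ("intervertebral", "vertebra_foramen")
    rows = {}
    for rep in sys_reports:
        if rep.image_id not in refs:
            continue
        sys_map = _measurement_map(rep)
        ref_map = _measurement_map(refs[rep.image_id])
        row = {}
        for kind in kinds:
            keys = sorted(
                k for k in sys_map.keys() & ref_map.keys() if k[0] == kind
            )
            if len(keys) < 2:
                row[kind] = np.nan
                continue
            r = ppmcc([sys_map[k] for k in keys], [ref_map[k] for k in keys])
            row[kind] = np.nan if r is None else r
        rows[rep.image_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(kinds))
    df.loc["Average"] = df.mean(skipna=True)
    return df
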