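"""Vertebra / neural-foramen detections and the pluggable detector contract.

The measurement pipeline is detector-agnostic: anything implementing
:class:`Detector` can supply labeled bounding boxes for the cervical vertebrae
(C2-C7) and neural foramina. Two implementations ship here:

* :class:`AnnotationDetector` — replays YOLO-format label files (e.g. the
  output of an externally trained YOLOv8 model, or manual annotations);
* :class:`OracleDetector` — returns the exact ground-truth boxes of a
  synthetic phantom, isolating the measurement stages from detector error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Protocol, Sequence, runtime_checkable

import numpy as np

from .image_io import (
    ALL_LABELS,
    DEFAULT_CLASS_MAP,
    FORAMEN_LABEL,
    VERTEBRA_LABELS,
    AnnotationRecord,
    read_yolo_labels,
    validate_gray,
)

if TYPE_CHECKING:  # pragma: no cover
    from .spine_crop import CropRegion
    from .synthetic import PhantomGroundTruth


@dataclass(frozen=True)
class Detection:
    """A labeled, half-open pixel bounding box with a confidence in [0, 1]."""

    label: str
    box: tuple[float, float, float, float]  # (x_min, y_min, x_max, y_max)
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.box
        return (x1 - x0) * (y1 - y0)


@runtime_checkable
class Detector(Protocol):
    """Detector contract: return detections in the given image's coordinates.

    ``frame`` tells implementations that ``image`` is a sub-window of a larger
    scene (the spine crop); implementations that already work in the image's
    own frame may ignore it.
    """

    def detect(
        self, image: np.ndarray, frame: "CropRegion | None" = None
    ) -> list[Detection]: ...


class AnnotationDetector:
    """Detector backed by YOLO-format annotation records (confidence 1.0).

    The records are assumed to be normalized to the image handed to
    :meth:`detect`.
    """

    def __init__(
        self,
        records: Sequence[AnnotationRecord],
        class_map: dict[int, str] | None = None,
    ) -> None:
        self.records = list(records)
        self.class_map = dict(class_map or DEFAULT_CLASS_MAP)

    @classmethod
    def from_file(
        cls, path: str | Path, class_map: dict[int, str] | None = None
    ) -> "AnnotationDetector":
        cmap = dict(class_map or DEFAULT_CLASS_MAP)
        return cls(read_yolo_labels(path, n_classes=max(cmap) + 1), cmap)

    def detect(self, image: np.ndarray, frame: "CropRegion | None" = None) -> list[Detection]:
        h, w = validate_gray(image).shape
        out = []
        for rec in self.records:
            label = self.class_map[rec.class_id]
            out.append(Detection(label=label, box=rec.to_pixel_box(w, h), confidence=1.0))
        return out


class OracleDetector:
    """Detector that replays a synthetic phantom's ground-truth boxes.

    Boxes are stored in full-phantom coordinates; when a crop ``frame`` is
    given they are translated into the crop and clipped, and boxes that fall
    entirely outside it are dropped.
    """

    def __init__(self, truth: "PhantomGroundTruth", confidence: float = 1.0) -> None:
        self.truth = truth
        self.confidence = confidence

    def detect(self, image: np.ndarray, frame: "CropRegion | None" = None) -> list[Detection]:
        h, w = validate_gray(image).shape
        labeled: list[tuple[str, tuple[float, float, float, float]]] = [
            (lab, box) for lab, box in self.truth.boxes.items()
        ]
        labeled += [(FORAMEN_LABEL, box) for box in self.truth.foramen_boxes]
        dx = dy = 0.0
        if frame is not None:
            dx, dy = float(frame.x_min), float(frame.y_min)
        out = []
        for lab, (x0, y0, x1, y1) in labeled:
            bx0 = max(x0 - dx, 0.0)
            by0 = max(y0 - dy, 0.0)
            bx1 = min(x1 - dx, float(w))
            by1 = min(y1 - dy, float(h))
            if bx1 - bx0 >= 1.0 and by1 - by0 >= 1.0:
                out.append(Detection(label=lab, box=(bx0, by0, bx1, by1), confidence=self.confidence))
        return out


def resolve_duplicates(detections: Sequence[Detection]) -> list[Detection]:
    """Keep the best detection per vertebra label; foramina are all kept.

    "Best" is highest confidence, ties broken by larger box area, then by
    input order. Idempotent; survivor order follows the input.
    """
    best: dict[str, tuple[float, float, int]] = {}
    for i, det in enumerate(detections):
        if det.label == FORAMEN_LABEL:
            continue
        key = (det.confidence, det.area, -i)  # -i: earlier wins ties
        if det.label not in best or key > best[det.label]:
            best[det.label] = key
    out = []
    for i, det in enumerate(detections):
        if det.label == FORAMEN_LABEL or best[det.label] == (det.confidence, det.area, -i):
            out.append(det)
    return out


@dataclass
class LevelPairing:
    """Adjacent vertebra pairs plus the foramen-to-vertebra assignment."""

    vertebra_pairs: list[tuple[str, str]] = field(default_factory=list)
    foramen_assignment: list[tuple[Detection, str | None]] = field(default_factory=list)


def pair_levels(detections: Sequence[Detection]) -> LevelPairing:
    """Pair adjacent detected vertebrae and assign each foramen to a vertebra.

    Expects duplicate-free vertebra detections. Only anatomically adjacent
    pairs (C2-C3 ... C6-C7) with both members detected are formed. Each
    foramen is assigned to the vertebra whose box center is nearest its own
    box center (unassigned if no vertebra was detected).
    """
    vertebrae = {d.label: d for d in detections if d.label != FORAMEN_LABEL}
    if len(vertebrae) != sum(1 for d in detections if d.label != FORAMEN_LABEL):
        raise ValueError("duplicate vertebra labels: run resolve_duplicates first")
    pairs = [
        (a, b)
        for a, b in zip(VERTEBRA_LABELS[:-1], VERTEBRA_LABELS[1:])
        if a in vertebrae and b in vertebrae
    ]
    assignment: list[tuple[Detection, str | None]] = []
    for det in detections:
        if det.label != FORAMEN_LABEL:
            continue
        if not vertebrae:
            assignment.append((det, None))
            continue
        fx, fy = det.center
        nearest = min(
            vertebrae.values(),
            key=lambda v: (v.center[0] - fx) ** 2 + (v.center[1] - fy) ** 2,
        )
        assignment.append((det, nearest.label))
    return LevelPairing(vertebra_pairs=pairs, foramen_assignment=assignment)
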