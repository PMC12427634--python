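"""Raster, annotation and report I/O.

All geometry in this package uses one convention: ``x`` is the column index,
``y`` the row index, origin at the top-left, 0-based, and bounding boxes are
half-open ``[x_min, x_max) x [y_min, y_max)``.

Images are 8-bit grayscale NumPy arrays (``uint8``, shape ``(height, width)``).
Detector annotations use the YOLO text-label format, one file per image with
lines ``class x_center y_center width height`` normalized to ``[0, 1]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .detection import Detection
    from .measure import MeasurementReport

VERTEBRA_LABELS: tuple[str, ...] = ("C2", "C3", "C4", "C5", "C6", "C7")
FORAMEN_LABEL = "FORAMEN"
ALL_LABELS: tuple[str, ...] = VERTEBRA_LABELS + (FORAMEN_LABEL,)

#: Default class-id -> anatomical label map for YOLO annotation files.
DEFAULT_CLASS_MAP: dict[int, str] = {i: lab for i, lab in enumerate(ALL_LABELS)}


class ImageReadError(ValueError):
    """Raised when an image file cannot be read as a single grayscale frame."""


class YoloParseError(ValueError):
    """Raised on malformed YOLO label lines; carries the 1-based line number."""


def validate_gray(image: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a uint8 grayscale image.

    Accepts any integer (or exactly-integral float) 2-D array with values in
    [0, 255]; returns a ``uint8`` view/copy.
    """
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise ValueError("grayscale values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG (8/16-bit gray or RGB) or single-frame DICOM image.

    RGB is collapsed to luminance; >8-bit data is linearly rescaled so the
    dtype's full range maps onto [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"cannot read image {path}: file does not exist")
    if path.suffix.lower() in {".dcm", ".dicom"}:
        return _read_dicom(path)
    try:
        with Image.open(path) as im:
            n_frames = getattr(im, "n_frames", 1)
            if n_frames > 1:
                raise ImageReadError(f"cannot read image {path}: multi-frame files are unsupported")
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.float64)
                arr = arr / 65535.0 * 255.0
                arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
            else:
                arr = np.asarray(im.convert("L"))
    except ImageReadError:
        raise
    except Exception as exc:
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ImageReadError(f"cannot read image {path}: empty raster")
    return validate_gray(arr)


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise ImageReadError(
            f"cannot read image {path}: DICOM support requires the 'dicom' extra (pydicom)"
        ) from exc
    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ImageReadError(f"cannot read image {path}: multi-frame DICOM is unsupported")
    arr = arr.astype(np.float64)
    if arr.max() > 255:
        bits = int(getattr(ds, "BitsStored", 16))
        arr = arr / (2**bits - 1) * 255.0
    return validate_gray(np.clip(np.rint(arr), 0, 255).astype(np.uint8))


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a grayscale image as 8-bit PNG (or any Pillow-supported format)."""
    Image.fromarray(validate_gray(image), mode="L").save(Path(path))


@dataclass(frozen=True)
class AnnotationRecord:
    """One YOLO-format annotation: class id plus normalized box geometry."""

    class_id: int
    x_center: float
    y_center: float
    box_width: float
    box_height: float

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        for name in ("x_center", "y_center", "box_width", "box_height"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.box_width <= 0 or self.box_height <= 0:
            raise ValueError("box_width and box_height must be > 0")

    def to_pixel_box(self, width: int, height: int) -> tuple[float, float, float, float]:
        """Denormalize to a half-open pixel box (x_min, y_min, x_max, y_max)."""
        w = self.box_width * width
        h = self.box_height * height
        x0 = self.x_center * width - w / 2
        y0 = self.y_center * height - h / 2
        return (x0, y0, x0 + w, y0 + h)


def read_yolo_labels(path: str | Path, n_classes: int = len(ALL_LABELS)) -> list[AnnotationRecord]:
    """Parse a YOLO label file; one record per non-empty line, order preserved."""
    records: list[AnnotationRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise YoloParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            class_id = int(parts[0])
            geom = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise YoloParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
        if class_id >= n_classes:
            raise YoloParseError(f"{path}:{lineno}: class id {class_id} >= n_classes={n_classes}")
        try:
            records.append(AnnotationRecord(class_id, *geom))
        except ValueError as exc:
            raise YoloParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_yolo_labels(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    lines = [
        f"{r.class_id} {r.x_center:.6f} {r.y_center:.6f} {r.box_width:.6f} {r.box_height:.6f}"
        for r in records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# --- measurement reports ----------------------------------------------------

_CSV_COLUMNS = ["image_id", "kind", "level_pair", "distance_px"]


def write_report(report: "MeasurementReport", path: str | Path, format: str = "csv") -> None:
    """Serialize a measurement report; CSV is row-per-measurement, JSON is full."""
    path = Path(path)
    if format == "csv":
        rows = [
            {
                "image_id": report.image_id,
                "kind": m.kind,
                "level_pair": f"{m.from_label}-{m.to_label}",
                "distance_px": m.distance,
            }
            for m in report.measurements
        ]
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(report.to_dict(), sort_keys=True, indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str | None = None) -> "MeasurementReport":
    """Read back a report written by :func:`write_report`.

    CSV reports only carry (kind, level pair, distance); point coordinates and
    provenance survive the JSON route only.
    """
    from .measure import DistanceMeasurement, MeasurementReport

    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        d = json.loads(path.read_text())
        measurements = [
            DistanceMeasurement(
                kind=m["kind"],
                from_label=m["from_label"],
                to_label=m["to_label"],
                p1=tuple(m["p1"]),
                p2=tuple(m["p2"]),
                distance=m["distance_px"],
            )
            for m in d["measurements"]
        ]
        return MeasurementReport(
            image_id=d["image_id"],
            measurements=measurements,
            missing_levels=list(d.get("missing_levels", [])),
            notes=list(d.get("notes", [])),
            provenance=dict(d.get("provenance", {})),
        )
    df = pd.read_csv(path)
    measurements = []
    image_id = ""
    for _, row in df.iterrows():
        image_id = str(row["image_id"])
        frm, to = str(row["level_pair"]).split("-", 1)
        d = float(row["distance_px"])
        measurements.append(
            DistanceMeasurement(
                kind=str(row["kind"]), from_label=frm, to_label=to,
                p1=(0.0, 0.0), p2=(d, 0.0), distance=d,
            )
        )
    return MeasurementReport(image_id=image_id, measurements=measurements)


def render_overlay(
    image: np.ndarray,
    detections: Sequence["Detection"] = (),
    measurements: "MeasurementReport | None" = None,
) -> np.ndarray:
    """Draw detection boxes, ``"<label> <conf>"`` tags and measurement segments.

    Returns a new grayscale image; with no detections and no measurements the
    output is a pixel-identical copy of the input.
    """
    im = Image.fromarray(validate_gray(image), mode="L").copy()
    draw = ImageDraw.Draw(im)
    for det in detections:
        x0, y0, x1, y1 = det.box
        draw.rectangle([x0, y0, x1 - 1, y1 - 1], outline=255)
        draw.text((x0 + 2, max(0.0, y0 - 11)), f"{det.label} {det.confidence:.2f}", fill=255)
    if measurements is not None:
        for m in measurements.measurements:
            draw.line([tuple(m.p1), tuple(m.p2)], fill=255, width=1)
            for px, py in (m.p1, m.p2):
                draw.ellipse([px - 1, py - 1, px + 1, py + 1], fill=255)
    return np.asarray(im)
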