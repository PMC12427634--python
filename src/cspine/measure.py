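"""Reference-point localization and automated distance measurement.

Given a detected vertebra (or foramen) region of interest, the stage

1. enhances the ROI (percentile contrast stretch, Gaussian blur, Otsu
   binarization, morphological opening/closing),
2. extracts the largest 8-connected white component,
3. finds the four directional extreme points of the component — the
   foreground pixels extremal along the diagonal functionals ``y - x`` and
   ``y + x``, which approximate the vertebral-body corners regardless of
   tilt,
4. intersects the mid-column between the two bottom (top) corners with the
   lower (upper) white boundary, yielding the lower (upper) reference point.

The intervertebral distance at a level is the Euclidean distance from the
upper vertebra's lower reference point to the lower vertebra's upper
reference point; the vertebra-to-foramen distance applies the same mid-line
construction sideways, between the facing lateral boundaries of the two
structures. All distances are reported in pixels of the standardized frame
(an optional mm-per-pixel scale converts them on output).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .detection import FORAMEN_LABEL, VERTEBRA_LABELS, Detection, Detector, pair_levels, resolve_duplicates
from .image_io import validate_gray
from .preprocess import PreprocessConfig, binarize_pipeline, otsu_threshold, resize_to_standard
from .spine_crop import crop_spine

Point = tuple[float, float]

_CROSS = ndimage.generate_binary_structure(2, 1)  # 3x3 cross
_EIGHT = ndimage.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass
class MeasureConfig:
    """ROI enhancement and measurement parameters.

    stretch_percentiles
        Intensity percentiles mapped to 0 and 255 by the contrast stretch.
    blur_sigma
        Gaussian blur scale (pixels) applied before binarization.
    roi_margin
        Fractional expansion of the detection box per side before
        measurement; detector boxes may clip the cortical edge that defines
        the reference point.
    mm_per_pixel
        Optional physical scale; when set, distances are additionally
        reported in millimeters in the report dictionary.
    """

    stretch_percentiles: tuple[float, float] = (2.0, 98.0)
    blur_sigma: float = 1.0
    roi_margin: float = 0.10
    mm_per_pixel: float | None = None


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pad_x: int = 50
    pad_y: int = 50
    measure: MeasureConfig = field(default_factory=MeasureConfig)


@dataclass
class ComponentMask:
    """A single 8-connected foreground component, ROI-local with an offset."""

    pixels: np.ndarray  # bool, ROI-local
    component_area: int
    offset: tuple[int, int] = (0, 0)  # (x, y) of the ROI origin in the full image

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.component_area < 1:
            raise ValueError("component_area must be >= 1")


@dataclass
class ReferencePointSet:
    """Directional extrema plus the upper/lower mid-column reference points."""

    bottom_left: Point
    bottom_right: Point
    top_left: Point
    top_right: Point
    lower_ref: Point
    upper_ref: Point
    fallback_used: bool = False


@dataclass
class DistanceMeasurement:
    kind: str  # "intervertebral" | "vertebra_foramen"
    from_label: str
    to_label: str
    p1: Point
    p2: Point
    distance: float

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "from_label": self.from_label,
            "to_label": self.to_label,
            "p1": [float(self.p1[0]), float(self.p1[1])],
            "p2": [float(self.p2[0]), float(self.p2[1])],
            "distance_px": float(self.distance),
        }


@dataclass
class MeasurementReport:
    image_id: str
    measurements: list[DistanceMeasurement] = field(default_factory=list)
    missing_levels: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "measurements": [m.to_dict() for m in self.measurements],
            "missing_levels": list(self.missing_levels),
            "notes": list(self.notes),
            "provenance": self.provenance,
        }


# --- ROI enhancement --------------------------------------------------------


def enhance_roi(roi: np.ndarray, config: MeasureConfig | None = None) -> np.ndarray:
    """Contrast stretch -> Gaussian blur -> Otsu -> opening + closing.

    Returns a {0, 255} binary image of the ROI's bright structure.
    """
    cfg = config or MeasureConfig()
    img = validate_gray(roi)
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"ROI too small for measurement: {img.shape}")
    lo_p, hi_p = cfg.stretch_percentiles
    lo, hi = np.percentile(img, [lo_p, hi_p])
    if hi <= lo:
        lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise ValueError("degenerate ROI: constant intensity")
    stretched = np.clip((img.astype(np.float64) - lo) / (hi - lo) * 255.0, 0, 255)
    blurred = ndimage.gaussian_filter(stretched, sigma=cfg.blur_sigma, mode="nearest")
    blurred_u8 = np.rint(blurred).astype(np.uint8)
    t = otsu_threshold(blurred_u8)
    mask = blurred_u8 > t
    # edge-replicated borders: structures touching the ROI edge must not be
    # eroded away by the implicit all-black frame
    padded = np.pad(mask, 1, mode="edge")
    padded = ndimage.binary_opening(padded, structure=_CROSS)
    padded = ndimage.binary_closing(padded, structure=_CROSS)
    mask = padded[1:-1, 1:-1]
    if not mask.any():
        raise ValueError("degenerate ROI: no foreground after morphology")
    return np.where(mask, 255, 0).astype(np.uint8)


def largest_component(binary: np.ndarray, offset: tuple[int, int] = (0, 0)) -> ComponentMask:
    """Largest 8-connected white component; ties go to the component whose
    first pixel in row-major order comes first."""
    arr = validate_gray(binary)
    fg = arr > 0
    if not fg.any():
        raise ValueError("no component: image is all black")
    labels, n = ndimage.label(fg, structure=_EIGHT)
    areas = np.bincount(labels.ravel())[1:]
    max_area = areas.max()
    tied = np.flatnonzero(areas == max_area) + 1
    if tied.size == 1:
        winner = int(tied[0])
    else:
        flat = labels.ravel()
        winner = int(min(tied, key=lambda lab: np.argmax(flat == lab)))
    mask = labels == winner
    return ComponentMask(pixels=mask, component_area=int(max_area), offset=offset)


# --- landmarks --------------------------------------------------------------


def _argopt(xs: np.ndarray, ys: np.ndarray, score: np.ndarray, maximize: bool) -> Point:
    """Extremal foreground pixel; ties -> smaller y, then smaller x."""
    best = score.max() if maximize else score.min()
    cand = np.flatnonzero(score == best)
    order = np.lexsort((xs[cand], ys[cand]))
    i = cand[order[0]]
    return (float(xs[i]), float(ys[i]))


def directional_extrema(mask: ComponentMask) -> tuple[Point, Point, Point, Point]:
    """Corner-like extreme points (bottom-left, bottom-right, top-left,
    top-right) in full-image coordinates.

    bottom_left maximizes ``y - x``, bottom_right maximizes ``y + x``,
    top_left minimizes ``y + x``, top_right minimizes ``y - x``.
    """
    ys, xs = np.nonzero(mask.pixels)
    ox, oy = mask.offset
    diff = ys.astype(np.int64) - xs
    summ = ys.astype(np.int64) + xs
    bl = _argopt(xs, ys, diff, True)
    br = _argopt(xs, ys, summ, True)
    tl = _argopt(xs, ys, summ, False)
    tr = _argopt(xs, ys, diff, False)
    return tuple((p[0] + ox, p[1] + oy) for p in (bl, br, tl, tr))  # type: ignore[return-value]


def _round_half_even(v: float) -> int:
    return int(np.round(v))


def _nearest_foreground_column(pixels: np.ndarray, col: int) -> int:
    occupied = np.flatnonzero(pixels.any(axis=0))
    return int(occupied[np.argmin(np.abs(occupied - col))])


def _nearest_foreground_row(pixels: np.ndarray, row: int) -> int:
    occupied = np.flatnonzero(pixels.any(axis=1))
    return int(occupied[np.argmin(np.abs(occupied - row))])


def reference_points(mask: ComponentMask) -> ReferencePointSet:
    """Upper and lower reference points of a vertebral-body component.

    The mid-column between the two bottom corners is intersected with the
    lowest white pixel of that column (lower reference point, the "red dot");
    the construction mirrored at the top gives the upper reference point (the
    "blue dot"). Mid-columns are rounded half-to-even; if the rounded column
    contains no foreground (possible on concave masks) the nearest foreground
    column is used and flagged.
    """
    bl, br, tl, tr = directional_extrema(mask)
    ox, oy = mask.offset
    fallback = False

    # rounding happens in mask-local coordinates so the construction is
    # exactly translation-equivariant (half-to-even is not shift-invariant)
    col = _round_half_even((bl[0] + br[0]) / 2.0 - ox)
    if col < 0 or col >= mask.pixels.shape[1] or not mask.pixels[:, col].any():
        col = _nearest_foreground_column(mask.pixels, col)
        fallback = True
    lower = (float(col + ox), float(np.flatnonzero(mask.pixels[:, col])[-1] + oy))

    col = _round_half_even((tl[0] + tr[0]) / 2.0 - ox)
    if col < 0 or col >= mask.pixels.shape[1] or not mask.pixels[:, col].any():
        col = _nearest_foreground_column(mask.pixels, col)
        fallback = True
    upper = (float(col + ox), float(np.flatnonzero(mask.pixels[:, col])[0] + oy))

    return ReferencePointSet(
        bottom_left=bl, bottom_right=br, top_left=tl, top_right=tr,
        lower_ref=lower, upper_ref=upper, fallback_used=fallback,
    )


def _lateral_reference_point(mask: ComponentMask, side: str) -> Point:
    """Mid-row reference point on the left or right lateral boundary.

    The sideways analogue of :func:`reference_points`: the two corners of the
    requested side give a mid-row, whose intersection with that side's white
    boundary is the lateral reference point.
    """
    bl, br, tl, tr = directional_extrema(mask)
    ox, oy = mask.offset
    if side == "right":
        row = _round_half_even((tr[1] + br[1]) / 2.0 - oy)
    elif side == "left":
        row = _round_half_even((tl[1] + bl[1]) / 2.0 - oy)
    else:
        raise ValueError("side must be 'left' or 'right'")
    if row < 0 or row >= mask.pixels.shape[0] or not mask.pixels[row].any():
        row = _nearest_foreground_row(mask.pixels, row)
    cols = np.flatnonzero(mask.pixels[row])
    x = cols[-1] if side == "right" else cols[0]
    return (float(x + ox), float(row + oy))


def euclidean_distance(p1: Point, p2: Point) -> float:
    """Plane Euclidean distance ``sqrt((x2-x1)^2 + (y2-y1)^2)``."""
    return math.sqrt((p2[0] - p1[0]) ** 2 + (p2[1] - p1[1]) ** 2)


# --- measurements -----------------------------------------------------------


def measure_intervertebral(
    upper_mask: ComponentMask,
    lower_mask: ComponentMask,
    labels: tuple[str, str] = ("C2", "C3"),
) -> DistanceMeasurement:
    """Distance from the upper vertebra's lower reference point to the lower
    vertebra's upper reference point."""
    p1 = reference_points(upper_mask).lower_ref
    p2 = reference_points(lower_mask).upper_ref
    return DistanceMeasurement(
        kind="intervertebral", from_label=labels[0], to_label=labels[1],
        p1=p1, p2=p2, distance=euclidean_distance(p1, p2),
    )


def measure_vertebra_foramen(
    vertebra_mask: ComponentMask,
    foramen_mask: ComponentMask,
    labels: tuple[str, str] = ("C2", FORAMEN_LABEL),
) -> DistanceMeasurement:
    """Distance between the facing lateral-boundary midpoints of a vertebral
    body and a neural foramen.

    The facing sides are decided from the component centroids: the vertebra
    contributes its foramen-facing boundary point, the foramen its
    vertebra-facing (medial) one.
    """

    def centroid_x(m: ComponentMask) -> float:
        return float(np.nonzero(m.pixels)[1].mean()) + m.offset[0]

    if centroid_x(foramen_mask) >= centroid_x(vertebra_mask):
        p1 = _lateral_reference_point(vertebra_mask, "right")
        p2 = _lateral_reference_point(foramen_mask, "left")
    else:
        p1 = _lateral_reference_point(vertebra_mask, "left")
        p2 = _lateral_reference_point(foramen_mask, "right")
    return DistanceMeasurement(
        kind="vertebra_foramen", from_label=labels[0], to_label=labels[1],
        p1=p1, p2=p2, distance=euclidean_distance(p1, p2),
    )


# --- end-to-end pipeline ----------------------------------------------------


def _expand_box(
    box: tuple[float, float, float, float], margin: float, width: int, height: int
) -> tuple[int, int, int, int]:
    x0, y0, x1, y1 = box
    mx = (x1 - x0) * margin
    my = (y1 - y0) * margin
    return (
        max(int(math.floor(x0 - mx)), 0),
        max(int(math.floor(y0 - my)), 0),
        min(int(math.ceil(x1 + mx)), width),
        min(int(math.ceil(y1 + my)), height),
    )


def run_pipeline(
    image: np.ndarray,
    detector: Detector,
    config: PipelineConfig | None = None,
    image_id: str = "image",
) -> MeasurementReport:
    """Full measurement pipeline on one radiograph.

    binarize -> crop the spine region -> detect on the crop -> resolve
    duplicate vertebrae -> pair adjacent levels and foramina -> enhance each
    ROI and measure. Failures at individual levels are recorded in the
    report's notes and the pipeline continues; all coordinates are in the
    standardized (resized) image frame.
    """
    cfg = config or PipelineConfig()
    report = MeasurementReport(image_id=image_id, provenance=_provenance(cfg))

    gray = resize_to_standard(image, cfg.preprocess.target_size)
    try:
        binary = binarize_pipeline(gray, cfg.preprocess)
        region, crop = crop_spine(gray, binary, cfg.pad_x, cfg.pad_y)
    except ValueError as exc:
        report.notes.append(f"pipeline failed before measurement: {exc}")
        report.missing_levels = list(VERTEBRA_LABELS)
        return report

    detections = resolve_duplicates(detector.detect(crop, frame=region))
    pairing = pair_levels(detections)
    report.missing_levels = [
        lab for lab in VERTEBRA_LABELS if lab not in {d.label for d in detections}
    ]

    h, w = crop.shape
    masks: dict[int, ComponentMask] = {}

    def component_for(det: Detection) -> ComponentMask | None:
        key = id(det)
        if key in masks:
            return masks[key]
        x0, y0, x1, y1 = _expand_box(det.box, cfg.measure.roi_margin, w, h)
        roi = crop[y0:y1, x0:x1]
        try:
            binary_roi = enhance_roi(roi, cfg.measure)
            comp = largest_component(
                binary_roi, offset=(region.x_min + x0, region.y_min + y0)
            )
        except ValueError as exc:
            report.notes.append(f"{det.label}: {exc}")
            return None
        masks[key] = comp
        return comp

    by_label = {d.label: d for d in detections if d.label != FORAMEN_LABEL}
    for a, b in pairing.vertebra_pairs:
        ca = component_for(by_label[a])
        cb = component_for(by_label[b])
        if ca is None or cb is None:
            continue
        report.measurements.append(measure_intervertebral(ca, cb, (a, b)))
    for det, assigned in pairing.foramen_assignment:
        if assigned is None:
            report.notes.append("FORAMEN: no vertebra to pair with")
            continue
        cv = component_for(by_label[assigned])
        cf = component_for(det)
        if cv is None or cf is None:
            continue
        report.measurements.append(
            measure_vertebra_foramen(cv, cf, (assigned, FORAMEN_LABEL))
        )

    if cfg.measure.mm_per_pixel is not None:
        report.provenance["mm_per_pixel"] = cfg.measure.mm_per_pixel
    return report


def _provenance(cfg: PipelineConfig) -> dict:
    d = {
        "preprocess": asdict(cfg.preprocess),
        "pad_x": cfg.pad_x,
        "pad_y": cfg.pad_y,
        "measure": asdict(cfg.measure),
    }
    # tuples -> lists for stable JSON round-trips
    d["measure"]["stretch_percentiles"] = list(cfg.measure.stretch_percentiles)
    return d
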