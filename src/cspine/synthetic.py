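"""Synthetic lateral cervical-spine phantoms with analytically known geometry.

Real annotated cervical radiographs are scarce and not redistributable, so
every pipeline stage here is exercised on phantoms: six individually tilted
bright vertebral bodies (C2-C7, rendered as rotated rounded rectangles)
stacked along a mildly curved, lordosis-like axis and separated by known
gaps, with a posterior ellipse per level standing in for the neural-foramen
region, a mid-intensity soft-tissue band, a smooth illumination gradient,
additive Gaussian noise and salt-and-pepper noise.

Ground truth — bounding boxes, upper/lower edge midpoints, facing lateral
boundary points, and the distances between them — is computed analytically
from the pre-noise geometry, never re-measured from the rendered raster, so
it is an uncontaminated oracle for the measurement pipeline. Shape membership
is evaluated at integer pixel indices, so analytic edge coordinates and
raster boundary indices agree to within a pixel.

A phantom abstracts away much of real radiography: no projective overlap of
shoulders or mandible, no trabecular texture, no pathology, no detector
blur. It validates geometry and robustness to the modeled noise, not
clinical performance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_io import (
    ALL_LABELS,
    FORAMEN_LABEL,
    VERTEBRA_LABELS,
    AnnotationRecord,
    write_image,
    write_yolo_labels,
)
from .measure import euclidean_distance

Box = tuple[int, int, int, int]
Point = tuple[float, float]


@dataclass
class PhantomSpec:
    """Generation parameters; defaults emulate a 512x512 lateral radiograph.

    Intensities are on the 8-bit scale: dark air/background (40), mid
    soft tissue (100), bright cortical bone (190). Gaussian noise sigma 6 and
    a 0.2% salt-and-pepper fraction approximate quantum mottle and impulse
    noise; the illumination gradient (amplitude 20) models heel-effect
    shading across the field.
    """

    image_size: int = 512
    n_vertebrae: int = 6
    body_width: tuple[float, float] = (85.0, 110.0)
    body_height: tuple[float, float] = (40.0, 52.0)
    gap_range: tuple[float, float] = (5.0, 25.0)
    tilt_range: tuple[float, float] = (-10.0, 10.0)
    corner_radius: float = 6.0
    curvature_amplitude: float = 15.0
    foramen_offset: float = 35.0
    foramen_axes: tuple[float, float] = (10.0, 14.0)
    intensity_background: int = 40
    intensity_soft: int = 100
    intensity_bone: int = 190
    intensity_foramen: int = 170
    illumination_amplitude: float = 20.0
    gaussian_noise_sigma: float = 6.0
    salt_pepper_fraction: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 2:
            raise ValueError("n_vertebrae must be >= 2")
        if self.gap_range[0] <= 0:
            raise ValueError("gaps must be positive")
        if not (self.intensity_bone > self.intensity_soft > self.intensity_background):
            raise ValueError("intensities must satisfy bone > soft tissue > background")

    def labels(self) -> list[str]:
        if self.n_vertebrae <= len(VERTEBRA_LABELS):
            return list(VERTEBRA_LABELS[: self.n_vertebrae])
        return list(VERTEBRA_LABELS) + [
            f"V{i}" for i in range(len(VERTEBRA_LABELS), self.n_vertebrae)
        ]


@dataclass
class PhantomGroundTruth:
    """Analytic pre-noise geometry of one phantom."""

    boxes: dict[str, Box]
    foramen_boxes: list[Box]
    reference_points: dict[str, dict[str, Point]]  # upper / lower / lateral per vertebra
    foramen_centers: list[Point]
    foramen_medial_points: list[Point]
    intervertebral_distances: dict[str, float]  # "C2-C3" -> px
    vertebra_foramen_distances: dict[str, float]  # per vertebra label
    body_mask: np.ndarray  # bool, union of the vertebral bodies
    gaps: list[float] = field(default_factory=list)
    tilts_deg: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "boxes": {k: list(map(int, v)) for k, v in self.boxes.items()},
            "foramen_boxes": [list(map(int, b)) for b in self.foramen_boxes],
            "reference_points": {
                k: {n: [float(p[0]), float(p[1])] for n, p in pts.items()}
                for k, pts in self.reference_points.items()
            },
            "foramen_centers": [[float(x), float(y)] for x, y in self.foramen_centers],
            "foramen_medial_points": [
                [float(x), float(y)] for x, y in self.foramen_medial_points
            ],
            "intervertebral_distances": {
                k: float(v) for k, v in self.intervertebral_distances.items()
            },
            "vertebra_foramen_distances": {
                k: float(v) for k, v in self.vertebra_foramen_distances.items()
            },
            "gaps": [float(g) for g in self.gaps],
            "tilts_deg": [float(t) for t in self.tilts_deg],
        }


def _rounded_rect_mask(
    X: np.ndarray, Y: np.ndarray, cx: float, cy: float,
    w: float, h: float, theta_deg: float, radius: float,
) -> np.ndarray:
    # signed-distance test of a rotated rounded rectangle at integer indices
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    u = (X - cx) * c + (Y - cy) * s
    v = -(X - cx) * s + (Y - cy) * c
    r = min(radius, w / 2, h / 2)
    qx = np.abs(u) - (w / 2 - r)
    qy = np.abs(v) - (h / 2 - r)
    d = np.hypot(np.maximum(qx, 0), np.maximum(qy, 0)) + np.minimum(np.maximum(qx, qy), 0)
    return d <= r


def _bbox(mask: np.ndarray) -> Box:
    ys, xs = np.nonzero(mask)
    return (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[np.ndarray, PhantomGroundTruth]:
    """Render one phantom radiograph and its analytic ground truth.

    Identical specs (including the seed) produce identical images and truth.
    Raises if the sampled geometry cannot fit inside the image.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_vertebrae
    S = spec.image_size
    labels = spec.labels()

    widths = rng.uniform(*spec.body_width, size=n)
    heights = rng.uniform(*spec.body_height, size=n)
    gaps = rng.uniform(*spec.gap_range, size=n - 1)
    tilts = rng.uniform(*spec.tilt_range, size=n)

    # vertical half-extent of each tilted body; stacking by extents keeps the
    # sampled gap as the true clearance between adjacent bodies, so bodies
    # never interpenetrate regardless of tilt
    half_extents = (
        widths * np.abs(np.sin(np.radians(tilts))) + heights * np.cos(np.radians(tilts))
    ) / 2.0
    total_h = 2.0 * half_extents.sum() + gaps.sum()
    margin = 12.0
    if total_h > S - 2 * margin:
        raise ValueError("spec too large: vertebra stack exceeds the image height")
    start_y = (S - total_h) / 2.0

    # anterior bow: quadratic lateral offset of the body centers (lordosis)
    x_base = S / 2.0 - 30.0
    u = np.linspace(0.0, 1.0, n)
    x_centers = x_base - spec.curvature_amplitude * (1.0 - (2.0 * u - 1.0) ** 2)

    y_centers = np.empty(n)
    y_centers[0] = start_y + half_extents[0]
    for i in range(1, n):
        y_centers[i] = y_centers[i - 1] + half_extents[i - 1] + gaps[i - 1] + half_extents[i]

    fa, fb = spec.foramen_axes
    f_centers = [
        (x_centers[i] + widths[i] / 2.0 + spec.foramen_offset, y_centers[i])
        for i in range(n)
    ]
    lateral_max = max(fx + fa for fx, _ in f_centers)
    lateral_min = min(x_centers[i] - widths[i] / 2.0 for i in range(n))
    if lateral_min < margin or lateral_max > S - margin:
        raise ValueError("spec too large: geometry exceeds the image width")

    Y, X = np.mgrid[0:S, 0:S].astype(np.float64)
    body_masks = []
    for i in range(n):
        body_masks.append(
            _rounded_rect_mask(
                X, Y, x_centers[i], y_centers[i],
                widths[i], heights[i], tilts[i], spec.corner_radius,
            )
        )
    foramen_masks = [
        ((X - fx) / fa) ** 2 + ((Y - fy) / fb) ** 2 <= 1.0 for fx, fy in f_centers
    ]

    # --- analytic ground truth (pre-noise geometry) ---
    ref_points: dict[str, dict[str, Point]] = {}
    for i, lab in enumerate(labels):
        th = math.radians(tilts[i])
        c, s = math.cos(th), math.sin(th)
        hw, hh = widths[i] / 2.0, heights[i] / 2.0
        cx, cy = x_centers[i], y_centers[i]
        ref_points[lab] = {
            "upper": (cx + hh * s, cy - hh * c),
            "lower": (cx - hh * s, cy + hh * c),
            "lateral": (cx + hw * c, cy + hw * s),  # foramen-facing midpoint
        }
    iv_dist = {
        f"{labels[i]}-{labels[i + 1]}": euclidean_distance(
            ref_points[labels[i]]["lower"], ref_points[labels[i + 1]]["upper"]
        )
        for i in range(n - 1)
    }
    f_medial = [(fx - fa, fy) for fx, fy in f_centers]
    vf_dist = {
        labels[i]: euclidean_distance(ref_points[labels[i]]["lateral"], f_medial[i])
        for i in range(n)
    }
    truth = PhantomGroundTruth(
        boxes={labels[i]: _bbox(body_masks[i]) for i in range(n)},
        foramen_boxes=[_bbox(m) for m in foramen_masks],
        reference_points=ref_points,
        foramen_centers=list(f_centers),
        foramen_medial_points=f_medial,
        intervertebral_distances=iv_dist,
        vertebra_foramen_distances=vf_dist,
        body_mask=np.logical_or.reduce(body_masks),
        gaps=list(map(float, gaps)),
        tilts_deg=list(map(float, tilts)),
    )

    # --- render ---
    img = np.full((S, S), float(spec.intensity_background))
    band_x0 = max(lateral_min - 60.0, 0.0)
    band_x1 = min(lateral_max + 40.0, float(S))
    img[:, int(band_x0) : int(band_x1)] = spec.intensity_soft
    for m in body_masks:
        img[m] = spec.intensity_bone
    for m in foramen_masks:
        img[m] = spec.intensity_foramen
    if spec.illumination_amplitude:
        # heel-effect shading along the cranio-caudal (vertical) axis
        plane = Y / (S - 1) - 0.5
        img += spec.illumination_amplitude * 2.0 * plane
    if spec.gaussian_noise_sigma > 0:
        img += rng.normal(0.0, spec.gaussian_noise_sigma, size=img.shape)
    if spec.salt_pepper_fraction > 0:
        k = int(round(spec.salt_pepper_fraction * S * S))
        if k:
            idx = rng.choice(S * S, size=k, replace=False)
            vals = np.where(rng.random(k) < 0.5, 0.0, 255.0)
            img.ravel()[idx] = vals
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), truth


def export_phantom(
    image: np.ndarray,
    truth: PhantomGroundTruth,
    directory: str | Path,
    stem: str = "phantom",
) -> None:
    """Write the phantom PNG, its YOLO label file, and the ground-truth JSON.

    Uses the package class map (C2..C7 -> 0..5, FORAMEN -> 6); normalized
    boxes round-trip through the label reader to within 1 px.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    h, w = image.shape
    class_id = {lab: i for i, lab in enumerate(ALL_LABELS)}

    def to_record(cid: int, box: Box) -> AnnotationRecord:
        x0, y0, x1, y1 = box
        return AnnotationRecord(
            class_id=cid,
            x_center=(x0 + x1) / 2.0 / w,
            y_center=(y0 + y1) / 2.0 / h,
            box_width=(x1 - x0) / w,
            box_height=(y1 - y0) / h,
        )

    records = [to_record(class_id[lab], box) for lab, box in truth.boxes.items()]
    records += [to_record(class_id[FORAMEN_LABEL], box) for box in truth.foramen_boxes]

    write_image(image, directory / f"{stem}.png")
    write_yolo_labels(records, directory / f"{stem}.txt")
    (directory / f"{stem}_truth.json").write_text(
        json.dumps(truth.to_dict(), sort_keys=True, indent=2) + "\n"
    )
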