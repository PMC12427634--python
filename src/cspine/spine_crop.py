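"""Row-scan localization of the cervical-spine region in a binarized image.

The algorithm scans the binary image for the row with the fewest (but nonzero)
white pixels — the thinnest slice through the anatomy — takes the first and
last black-to-white transitions in that row, expands both ends through their
contiguous white runs, pads laterally, then bounds the spine vertically by the
first and last rows containing foreground inside the lateral band, pads again,
and crops. Padding defaults to 50 px on each side so no anatomy is lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import validate_gray


def _validate_binary(binary: np.ndarray) -> np.ndarray:
    arr = validate_gray(binary)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError("binary image must contain only values 0 and 255")
    return arr


@dataclass(frozen=True)
class CropRegion:
    """Half-open spine sub-window, with the padding already applied."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int
    pad_x: int
    pad_y: int
    anchor_row: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_min < self.x_max and 0 <= self.y_min < self.y_max):
            raise ValueError(f"invalid crop region {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def contains_box(self, box: tuple[float, float, float, float]) -> bool:
        x0, y0, x1, y1 = box
        return self.x_min <= x0 and x1 <= self.x_max and self.y_min <= y0 and y1 <= self.y_max


def row_white_counts(binary: np.ndarray) -> np.ndarray:
    """Number of white (255) pixels in each row."""
    return np.count_nonzero(_validate_binary(binary), axis=1)


def select_anchor_row(counts: np.ndarray) -> int:
    """Topmost row with the minimum strictly-positive white count.

    Empty rows are excluded: the reference row is the lowest-density slice
    *through the anatomy*, not blank background.
    """
    counts = np.asarray(counts)
    positive = counts > 0
    if not positive.any():
        raise ValueError("no foreground: all row counts are zero")
    min_pos = counts[positive].min()
    return int(np.argmax(counts == min_pos))


def locate_lateral_bounds(binary: np.ndarray, row: int, pad: int = 50) -> tuple[int, int]:
    """Lateral spine bounds from the anchor row, half-open and clamped.

    The first and last white pixels of the row are expanded through their
    contiguous white runs (disjoint runs are spanned first-to-last), then
    ``pad`` pixels are added on each side.
    """
    arr = _validate_binary(binary)
    line = arr[row] > 0
    white = np.flatnonzero(line)
    if white.size == 0:
        raise ValueError(f"no foreground: row {row} is all black")
    a = int(white[0])
    b = int(white[-1])
    while a > 0 and line[a - 1]:
        a -= 1
    while b < line.size - 1 and line[b + 1]:
        b += 1
    return (max(a - pad, 0), min(b + 1 + pad, line.size))


def locate_vertical_bounds(
    binary: np.ndarray, x_min: int, x_max: int, pad: int = 50
) -> tuple[int, int]:
    """First/last rows containing foreground within the lateral band, padded."""
    arr = _validate_binary(binary)
    band = arr[:, x_min:x_max]
    rows = np.flatnonzero(np.count_nonzero(band, axis=1))
    if rows.size == 0:
        raise ValueError(f"no foreground in column band [{x_min}, {x_max})")
    return (max(int(rows[0]) - pad, 0), min(int(rows[-1]) + 1 + pad, arr.shape[0]))


def crop_spine(
    image: np.ndarray, binary: np.ndarray, pad_x: int = 50, pad_y: int = 50
) -> tuple[CropRegion, np.ndarray]:
    """Locate the spine region in ``binary`` and crop it out of ``image``."""
    img = validate_gray(image)
    arr = _validate_binary(binary)
    if img.shape != arr.shape:
        raise ValueError(f"image {img.shape} and binary {arr.shape} dimensions differ")
    anchor = select_anchor_row(row_white_counts(arr))
    x_min, x_max = locate_lateral_bounds(arr, anchor, pad_x)
    y_min, y_max = locate_vertical_bounds(arr, x_min, x_max, pad_y)
    region = CropRegion(x_min, x_max, y_min, y_max, pad_x, pad_y, anchor)
    return region, img[y_min:y_max, x_min:x_max].copy()
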