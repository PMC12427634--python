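"""Radiograph preprocessing: standardization, denoising, contrast, binarization.

The stage turns a raw lateral cervical-spine radiograph into a binary image in
which the bright osseous structures are foreground, ready for the row-scan
spine localization. The chain is

    resize (512x512) -> median filter -> histogram equalization -> CLAHE
    -> adaptive threshold AND global Otsu mask

Every operation maps [0, 255] into [0, 255], uses edge replication at the
borders (avoiding dark halos that would corrupt the row-scan profile), and is
fully deterministic.

Histogram equalization and CLAHE share one lookup-table construction, so CLAHE
with a single tile and a non-binding clip limit reduces *exactly* to global
equalization. CLAHE is implemented here directly (clipped per-tile histograms
with uniform excess redistribution, bilinear blending between tile mappings)
rather than via a library routine so that this reduction, the uint8 mapping
semantics, and the clip/tile parameterization are exactly as documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .image_io import validate_gray


@dataclass
class PreprocessConfig:
    """Tunable parameters of the binarization chain.

    target_size
        Side length of the standardized square image (pixels).
    median_window
        Odd window of the median filter; 3 is the smallest window that removes
        salt-and-pepper noise while preserving cortical edges.
    use_hist_eq, use_clahe
        Individually switch the global and local contrast-enhancement steps.
    clahe_clip
        Contrast limit relative to a uniform histogram (OpenCV-style); bins
        are clipped at ``clip * n_tile_pixels / 256``.
    clahe_tiles
        Tile grid is ``tiles x tiles``.
    adaptive_block, adaptive_offset
        Local-mean window and offset of the adaptive threshold: a pixel is
        foreground iff ``value > local_mean - offset``.
    adaptive_method
        ``"mean"`` (default) or ``"gaussian"`` local weighting.
    """

    target_size: int = 512
    median_window: int = 3
    use_hist_eq: bool = True
    use_clahe: bool = True
    clahe_clip: float = 2.0
    clahe_tiles: int = 8
    adaptive_block: int = 31
    adaptive_offset: float = 5.0
    adaptive_method: str = "mean"

    def __post_init__(self) -> None:
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")
        for name in ("median_window", "adaptive_block"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {v}")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")
        if self.clahe_tiles < 1:
            raise ValueError("clahe_tiles must be >= 1")
        if self.adaptive_method not in ("mean", "gaussian"):
            raise ValueError("adaptive_method must be 'mean' or 'gaussian'")


def resize_to_standard(image: np.ndarray, target: int = 512) -> np.ndarray:
    """Resize to ``target x target`` with bilinear interpolation.

    Downscaling applies Gaussian anti-aliasing first so that sub-pixel
    structure averages rather than aliases. An image already at the target
    size is returned as an identical copy.
    """
    img = validate_gray(image)
    if target < 1:
        raise ValueError("target must be >= 1")
    if img.shape == (target, target):
        return img.copy()
    down = target < min(img.shape)
    out = _sk_resize(
        img.astype(np.float64),
        (target, target),
        order=1,
        mode="edge",
        anti_aliasing=down,
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def median_filter(image: np.ndarray, window: int = 3) -> np.ndarray:
    """Median of the ``window x window`` neighborhood, edges replicated."""
    img = validate_gray(image)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"median window must be odd and >= 3, got {window}")
    return ndimage.median_filter(img, size=window, mode="nearest")


def _he_lut(hist: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Equalization lookup table from a (possibly clipped, float) histogram.

    ``present`` marks gray levels that occur in the underlying image; the
    classical transfer function maps the lowest occurring level to 0:
    ``lut(v) = round((cdf(v) - cdf_min) / (n - cdf_min) * 255)``.
    """
    cdf = np.cumsum(hist)
    n = cdf[-1]
    first = int(np.argmax(present))
    cdf_min = cdf[first]
    if n <= cdf_min:  # single occurring gray level: identity
        return np.arange(256, dtype=np.uint8)
    lut = np.rint((cdf - cdf_min) / (n - cdf_min) * 255.0)
    return np.clip(lut, 0, 255).astype(np.uint8)


def equalize_hist(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization via the cumulative distribution.

    The mapping is monotone, so pixel rank order is preserved up to ties; a
    constant image is returned unchanged.
    """
    img = validate_gray(image)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    return _he_lut(hist, hist > 0)[img]


def _clahe_lut(hist: np.ndarray, clip: float) -> np.ndarray:
    n = hist.sum()
    limit = max(1.0, clip * n / 256.0)
    excess = np.maximum(hist - limit, 0.0).sum()
    clipped = np.minimum(hist, limit) + excess / 256.0
    return _he_lut(clipped, hist > 0)


def clahe(image: np.ndarray, clip: float = 2.0, tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is split into a ``tiles x tiles`` grid; each tile's histogram is
    clipped at ``clip`` times the uniform bin height with the excess spread
    evenly over all bins, and the per-tile equalization mappings are blended
    bilinearly between tile centers. ``tiles=1`` with a non-binding clip
    equals :func:`equalize_hist`.
    """
    img = validate_gray(image)
    if clip <= 0:
        raise ValueError("clip must be > 0")
    if tiles < 1:
        raise ValueError("tiles must be >= 1")
    h, w = img.shape
    th = -(-h // tiles)  # ceil division
    tw = -(-w // tiles)
    pad = np.pad(img, ((0, th * tiles - h), (0, tw * tiles - w)), mode="edge")

    luts = np.empty((tiles, tiles, 256), dtype=np.uint8)
    for i in range(tiles):
        for j in range(tiles):
            block = pad[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = np.bincount(block.ravel(), minlength=256).astype(np.float64)
            luts[i, j] = _clahe_lut(hist, clip)

    # fractional tile coordinates of every pixel, clamped at the border tiles
    ty = np.clip((np.arange(th * tiles) + 0.5) / th - 0.5, 0, tiles - 1)
    tx = np.clip((np.arange(tw * tiles) + 0.5) / tw - 0.5, 0, tiles - 1)
    i0 = np.floor(ty).astype(int)
    j0 = np.floor(tx).astype(int)
    i1 = np.minimum(i0 + 1, tiles - 1)
    j1 = np.minimum(j0 + 1, tiles - 1)
    wy = (ty - i0)[:, None]
    wx = (tx - j0)[None, :]

    v = pad
    i0c, i1c = i0[:, None], i1[:, None]
    j0c, j1c = j0[None, :], j1[None, :]
    out = (
        (1 - wy) * ((1 - wx) * luts[i0c, j0c, v] + wx * luts[i0c, j1c, v])
        + wy * ((1 - wx) * luts[i1c, j0c, v] + wx * luts[i1c, j1c, v])
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)[:h, :w]


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's global threshold.

    Returns the ``t`` maximizing the between-class variance
    ``w0*w1*(mu0-mu1)**2`` of the partition ``{v <= t} / {v > t}``
    (equivalently minimizing the within-class variance ``w0*s0^2 + w1*s1^2``).
    Ties are broken toward the lowest maximizing threshold.
    """
    img = validate_gray(image)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 distinct values")
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    omega0 = np.cumsum(p)
    mu_cum = np.cumsum(p * levels)
    mu_total = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu_cum) ** 2 / (omega0 * (1.0 - omega0))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    sigma_b[(omega0 <= 0) | (omega0 >= 1)] = -1.0
    return int(np.argmax(sigma_b))  # argmax returns the lowest maximizer


def adaptive_threshold(
    image: np.ndarray, block: int = 31, offset: float = 5.0, method: str = "mean"
) -> np.ndarray:
    """Local threshold: pixel is 255 iff ``value > local_mean - offset``.

    The local mean is taken over a ``block x block`` window (edge replicated);
    ``method="gaussian"`` uses a Gaussian-weighted mean of matching scale.
    """
    img = validate_gray(image)
    if block < 3 or block % 2 == 0:
        raise ValueError(f"adaptive block must be odd and >= 3, got {block}")
    if method == "mean":
        # exact integer box sums (separable) so boundary cases v == mean - offset
        # are decided without floating-point drift in the mean
        kernel = np.ones(block, dtype=np.int64)
        sums = ndimage.correlate1d(img.astype(np.int64), kernel, axis=0, mode="nearest")
        sums = ndimage.correlate1d(sums, kernel, axis=1, mode="nearest")
        n = block * block
        keep = img.astype(np.int64) * n > sums - offset * n
    elif method == "gaussian":
        local = ndimage.gaussian_filter(img.astype(np.float64), sigma=block / 6.0, mode="nearest")
        keep = img.astype(np.float64) > local - offset
    else:
        raise ValueError("method must be 'mean' or 'gaussian'")
    return np.where(keep, 255, 0).astype(np.uint8)


def binarize_pipeline(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Full preprocessing chain producing the spine-localization binary image.

    The adaptive mask keeps pixels that stand out from their neighborhood; the
    global Otsu mask (``value >= t``) restricts it to globally bright tissue.
    The result is their logical AND, with values in {0, 255} only.
    """
    cfg = config or PreprocessConfig()
    img = resize_to_standard(image, cfg.target_size)
    img = median_filter(img, cfg.median_window)
    if cfg.use_hist_eq:
        img = equalize_hist(img)
    if cfg.use_clahe:
        img = clahe(img, cfg.clahe_clip, cfg.clahe_tiles)
    t = otsu_threshold(img)
    adaptive = adaptive_threshold(img, cfg.adaptive_block, cfg.adaptive_offset, cfg.adaptive_method)
    mask = (adaptive > 0) & (img >= t)
    return np.where(mask, 255, 0).astype(np.uint8)
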