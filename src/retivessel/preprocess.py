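"""Fundus image preprocessing.

Turns a color fundus image plus a vessel segmentation (probability map in
[0, 1] or an already-binary mask) into the inputs the rest of the pipeline
consumes: the binary vessel mask with the optic-disc (OD) region removed,
the green and hue channel images, and a single-pixel-wide skeleton.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "binarize_otsu",
    "otsu_threshold",
    "is_binary",
    "apply_od_mask",
    "skeletonize",
    "extract_channels",
]

_N_BINS = 256


def _histogram_bins(prob: np.ndarray) -> np.ndarray:
    """Map probabilities in [0, 1] to integer bins 0..255."""
    p = np.asarray(prob, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability image")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("probability image values must lie in [0, 1]")
    return np.minimum((p * _N_BINS).astype(np.int64), _N_BINS - 1)


def otsu_threshold(prob: np.ndarray) -> int:
    """Otsu bin threshold over a 256-bin histogram of ``prob``.

    Returns the bin index ``t`` maximizing the between-class variance
    (equivalently minimizing intra-class variance); pixels in bins > t are
    foreground. Ties are broken toward the lowest threshold so the result
    is deterministic.

    Raises
    ------
    ValueError
        If the image occupies a single histogram bin (degenerate histogram:
        no threshold separates two classes).
    """
    bins = _histogram_bins(prob)
    hist = np.bincount(bins.ravel(), minlength=_N_BINS).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: probability image is constant")
    total = hist.sum()
    omega = np.cumsum(hist) / total                      # class-0 weight up to bin t
    mu = np.cumsum(hist * np.arange(_N_BINS)) / total    # first moment
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -np.inf
    # argmax takes the first (lowest) maximizer
    return int(np.argmax(sigma_b[:-1]))


def binarize_otsu(prob: np.ndarray) -> np.ndarray:
    """Binary vessel mask from a vessel probability image via Otsu's method."""
    t = otsu_threshold(prob)
    return _histogram_bins(prob) > t


def is_binary(image: np.ndarray) -> bool:
    """True if the segmentation image holds at most two distinct values."""
    return np.unique(np.asarray(image)).size <= 2


def apply_od_mask(mask: np.ndarray, center: tuple, radius: float) -> np.ndarray:
    """Remove mask pixels inside the optic-disc circle.

    Pixels with Euclidean distance to ``center`` (row, col) of at most
    ``radius`` become background; all others are unchanged. Idempotent.
    """
    if radius <= 0:
        raise ValueError("OD radius must be positive")
    rows, cols = np.ogrid[: mask.shape[0], : mask.shape[1]]
    inside = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
    out = np.asarray(mask, dtype=bool).copy()
    out[inside] = False
    return out


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a single-pixel-wide centerline.

    Idempotent; connected components of mask and skeleton correspond 1:1.
    An empty mask yields an empty skeleton.
    """
    return _sk_skeletonize(np.asarray(mask, dtype=bool))


def extract_channels(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Green channel and HSV hue channel of an RGB raster.

    Green keeps the input dtype/scale (0-255 for 8-bit input); hue lies in
    [0, 1) with achromatic pixels assigned hue 0.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB raster, got shape {rgb.shape}")
    green = rgb[:, :, 1]
    hue = rgb2hsv(rgb)[:, :, 0]
    # rgb2hsv can return exactly 1.0 only through rounding; fold into [0, 1)
    hue = np.where(hue >= 1.0, 0.0, hue)
    return green, hue
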