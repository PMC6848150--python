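"""Rolling-ball background subtraction (grayscale opening with a ball)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_OUTSIDE = 1.0e12  # sentinel pushing out-of-ball points out of min/max range


def ball_structure(radius_px: int) -> np.ndarray:
    """Non-flat ball structuring element of the given radius.

    Heights are ``sqrt(r^2 - d^2)`` inside the ball footprint and a large
    negative sentinel outside, which excludes those points from the grayscale
    min/max exactly.
    """
    r = int(radius_px)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dy * dy + dx * dx
    inside = d2 <= r * r
    z = np.full(inside.shape, -_OUTSIDE)
    z[inside] = np.sqrt(float(r * r) - d2[inside])
    return z


def rolling_ball_background(image: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Morphological background: grayscale opening with a ball element."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.any(img < 0):
        raise ValueError("image intensities must be nonnegative")
    if radius_px <= 0:
        raise ValueError("radius_px must be > 0")
    if 2 * radius_px + 1 > min(img.shape):
        raise ValueError(
            f"ball radius {radius_px} exceeds image extent {img.shape}: "
            "the structuring element must fit inside the image"
        )
    return ndimage.grey_opening(img, structure=ball_structure(radius_px), mode="reflect")


def subtract_background_rolling_ball(image: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Image minus its rolling-ball background; output is >= 0.

    Grayscale opening is anti-extensive so the clip only guards against
    floating-point round-off.
    """
    img = np.asarray(image, dtype=float)
    return np.clip(img - rolling_ball_background(img, radius_px), 0.0, None)
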