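"""Foreground cropping and size standardization.

Skull-stripped MR slices carry an exactly-zero background, so the brain is
isolated by the minimal bounding box of all pixels above a background
threshold, then resized to a fixed square (512x512 by default) before any
texture statistic is computed. Interpolation is bilinear by default: texture
matrices are sensitive to the blocky artifacts nearest-neighbor resampling
introduces.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .errors import EmptyForegroundError, ValidationError

__all__ = ["crop_to_bounding_box", "resize_image", "standardize"]

DEFAULT_SIDE = 512


def _as_image(img) -> np.ndarray:
    a = np.asarray(img, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValidationError(f"expected a nonempty 2D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError("image contains non-finite intensities")
    return a


def crop_to_bounding_box(img, background_level: float = 0.0) -> np.ndarray:
    """Return the minimal axis-aligned subimage holding every pixel above
    ``background_level``.

    No foreground pixel is discarded; an image whose pixels are all at or
    below the threshold raises :class:`EmptyForegroundError`.
    """
    a = _as_image(img)
    if background_level < 0:
        raise ValidationError("background_level must be >= 0")
    mask = a > background_level
    if not mask.any():
        raise EmptyForegroundError(
            f"no pixel exceeds background level {background_level!r}: empty foreground"
        )
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return a[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1].copy()


def resize_image(img, side: int = DEFAULT_SIDE, order: int = 1) -> np.ndarray:
    """Resize anisotropically to ``side x side`` pixels.

    The output never leaves the input intensity range (interpolation weights
    are convex; the result is clipped to the input min/max to also guard the
    anti-aliasing prefilter used when downscaling).
    """
    a = _as_image(img)
    if side < 2:
        raise ValidationError(f"target side must be >= 2, got {side}")
    if a.shape == (side, side):
        return a.copy()
    out = resize(a, (side, side), order=order, mode="reflect", preserve_range=True)
    return np.clip(out, a.min(), a.max())


def standardize(img, side: int = DEFAULT_SIDE, background_level: float = 0.0) -> np.ndarray:
    """Crop to the foreground bounding box, then resize (crop precedes resize)."""
    return resize_image(crop_to_bounding_box(img, background_level), side)
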