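"""Neutrosophic image domain.

A grayscale image g is mapped to three membership maps in [0, 1]:

* T (truth)          — min-max normalized local mean of g,
* I (indeterminacy)  — min-max normalized homogeneity delta = |g - local mean|,
* F (falsity)        — 1 - T.

The local mean is an a x a box average (a odd) with symmetric reflection
padding at the borders. Min/max statistics are per image: each map attains
both 0 and 1 somewhere, so T is invariant under affine intensity rescaling
of the input and I under intensity shifts.

Constant images make both normalizations degenerate (the local-mean and
delta maps are constant); they raise :class:`DegenerateImageError` rather
than yielding NaN maps, since every downstream texture feature would be
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import DegenerateImageError, ValidationError
from .preprocess import _as_image

__all__ = ["NeutrosophicImage", "local_mean", "to_neutrosophic"]

DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class NeutrosophicImage:
    """Triplet of T/I/F membership maps for one grayscale image."""

    T: np.ndarray
    I: np.ndarray  # noqa: E741 - field name mirrors the domain term
    F: np.ndarray
    window: int
    source_stats: dict = field(default_factory=dict)

    @property
    def maps(self) -> dict[str, np.ndarray]:
        return {"T": self.T, "I": self.I, "F": self.F}

    def __post_init__(self):
        if not (self.T.shape == self.I.shape == self.F.shape):
            raise ValidationError("T, I, F must share one shape")


def local_mean(img, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Mean of the ``window x window`` neighborhood around each pixel.

    ``window`` must be odd and positive; borders are handled by symmetric
    reflection padding, so ``window=1`` returns the image unchanged.
    """
    a = _as_image(img)
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    if window == 1:
        return a.copy()
    # scipy's 'reflect' mode is edge-inclusive symmetric padding (d c b a | a b c d)
    return uniform_filter(a, size=window, mode="reflect")


def to_neutrosophic(img, window: int = DEFAULT_WINDOW) -> NeutrosophicImage:
    """Map a grayscale image into the neutrosophic domain."""
    g = _as_image(img)
    gbar = local_mean(g, window)
    gbar_min, gbar_max = float(gbar.min()), float(gbar.max())
    if gbar_max <= gbar_min:
        raise DegenerateImageError(
            "degenerate truth map: local-mean map is constant (constant image?)"
        )
    delta = np.abs(g - gbar)
    d_min, d_max = float(delta.min()), float(delta.max())
    if d_max <= d_min:
        raise DegenerateImageError(
            "degenerate indeterminacy map: homogeneity map is constant"
        )
    T = (gbar - gbar_min) / (gbar_max - gbar_min)
    I = (delta - d_min) / (d_max - d_min)  # noqa: E741
    F = 1.0 - T
    stats = {
        "gbar_min": gbar_min,
        "gbar_max": gbar_max,
        "delta_min": d_min,
        "delta_max": d_max,
    }
    return NeutrosophicImage(T=T, I=I, F=F, window=window, source_stats=stats)
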