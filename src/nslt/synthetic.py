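"""Seeded two-class texture phantoms.

The generator emulates the texture contrast between low-grade ("benign")
and high-grade ("malignant") tumor slices with a model whose parameters
map monotonically onto the texture statistics the pipeline measures:
filtered Gaussian noise whose smoothing kernel width controls run-length
and co-occurrence structure, plus superimposed elliptical "lesion" blobs
whose contrast controls local heterogeneity.

A single ``separation`` dial in [0, 1] spreads the two classes apart:

* benign-like:    kernel sigma = 0.8 + 3.2 * separation (smooth, long runs)
* malignant-like: kernel sigma = 0.8, blob contrast 0.6 * separation

so ``separation = 0`` makes the two generative processes identical (a
permutation-null fixture) while the default 0.8 gives well-separated
classes. Every image sits inside a zero background margin (exercising the
bounding-box crop), lies in [0, 1], is non-constant, and its side is kept
dyadic-compatible for the Slantlet stage. Generation is fully reproducible
from the seed via per-image spawned substreams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError

__all__ = ["PhantomSpec", "generate_phantoms", "class_parameters"]

BENIGN, MALIGNANT = "benign", "malignant"


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic two-class image set."""

    n_per_class: int = 20
    side: int = 128
    separation: float = 0.8
    noise_sd: float = 0.05
    margin: int = 8
    blob_count: int = 3
    slt_scales: int = 2  # only used to validate dyadic compatibility
    imbalanced: bool = False  # mirror the 2.8:1 malignant:benign source ratio
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if not 0 <= self.separation <= 1:
            raise ValidationError("separation must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.side % 2**self.slt_scales or self.side <= 2 * self.margin + 4:
            raise ValidationError(
                f"side {self.side} must be a multiple of 2^{self.slt_scales} and "
                f"leave room inside margin {self.margin}")


def class_parameters(spec: PhantomSpec) -> dict[str, dict]:
    """Texture parameters per class implied by the separation dial."""
    return {
        BENIGN: {"sigma": 0.8 + 3.2 * spec.separation, "blob_contrast": 0.0},
        MALIGNANT: {"sigma": 0.8, "blob_contrast": 0.6 * spec.separation},
    }


def _one_phantom(rng: np.random.Generator, spec: PhantomSpec, params: dict) -> np.ndarray:
    inner = spec.side - 2 * spec.margin
    base = rng.standard_normal((inner, inner))
    tex = gaussian_filter(base, params["sigma"], mode="reflect")
    lo, hi = tex.min(), tex.max()
    tex = 0.15 + 0.7 * (tex - lo) / (hi - lo) if hi > lo else np.full_like(tex, 0.5)
    if params["blob_contrast"] > 0:
        yy, xx = np.mgrid[0:inner, 0:inner]
        for _ in range(spec.blob_count):
            cy, cx = rng.uniform(0.2 * inner, 0.8 * inner, size=2)
            ry, rx = rng.uniform(0.04 * inner, 0.12 * inner, size=2)
            theta = rng.uniform(0, np.pi)
            dy, dx = yy - cy, xx - cx
            u = dy * np.cos(theta) + dx * np.sin(theta)
            v = -dy * np.sin(theta) + dx * np.cos(theta)
            mask = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
            tex[mask] += params["blob_contrast"] * rng.choice((-1.0, 1.0))
    tex += rng.normal(0.0, spec.noise_sd, size=tex.shape)
    img = np.zeros((spec.side, spec.side))
    img[spec.margin : spec.margin + inner, spec.margin : spec.margin + inner] = (
        np.clip(tex, 0.02, 1.0))  # keep foreground strictly above the zero background
    return img


def generate_phantoms(spec: PhantomSpec) -> tuple[list[np.ndarray], list[str]]:
    """Generate the image set and its labels, reproducibly from the seed."""
    params = class_parameters(spec)
    if spec.imbalanced:
        counts = {BENIGN: spec.n_per_class, MALIGNANT: round(2.8 * spec.n_per_class)}
    else:
        counts = {BENIGN: spec.n_per_class, MALIGNANT: spec.n_per_class}
    total = sum(counts.values())
    streams = np.random.SeedSequence(spec.seed).spawn(total)
    images, labels = [], []
    k = 0
    for label in (BENIGN, MALIGNANT):
        for _ in range(counts[label]):
            images.append(_one_phantom(np.random.default_rng(streams[k]), spec, params[label]))
            labels.append(label)
            k += 1
    return images, labels
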