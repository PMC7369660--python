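"""Statistical texture matrices and their feature formulas.

Three second-order statistics are computed on a quantized image (integer
gray levels 1..N_g):

* GLCM — normalized frequencies of ordered gray-level pairs at a fixed
  displacement, yielding 10 features: homogeneity, energy, entropy,
  symmetry, contrast, correlation and the first four difference moments.
* GLRLM — counts of maximal runs of equal gray level along a direction,
  yielding 7 features: SRE, LRE, GLN, RP, RLN, LGRE, HGRE.
* GLDS — histogram of absolute gray-level differences at a displacement,
  yielding 4 features: ASM, contrast, mean, entropy.

Conventions (uniform across the module): entropies use the natural
logarithm with 0*ln 0 := 0; gray levels are indexed from 1 so the
low-gray-level emphasis 1/i^2 is defined; the GLCM is directional, not
symmetrized — symmetrizing would annihilate the symmetry feature and the
odd difference moments. In the neutrosophic pipeline each feature is
computed per membership map and aggregated by the T + I + F sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError, ValidationError
from .preprocess import _as_image

__all__ = [
    "QuantizedImage",
    "CooccurrenceMatrix",
    "RunLengthMatrix",
    "DifferenceHistogram",
    "FeatureVector",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "glcm_feature_set",
    "compute_glrlm",
    "glrlm_features",
    "glrlm_feature_set",
    "compute_glds",
    "glds_features",
    "aggregate_ns",
    "GLCM_OFFSETS",
    "GLRLM_DIRECTIONS",
]

GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees
GLRLM_DIRECTIONS = (0, 45, 90, 135)

GLCM_NAMES = ("hom", "enr", "ent", "sym", "con", "cor", "mom1", "mom2", "mom3", "mom4")
GLRLM_NAMES = ("sre", "lre", "gln", "rp", "rln", "lgre", "hgre")
GLDS_NAMES = ("asm", "con", "men", "ent")


class FeatureVector(dict):
    """Ordered named feature values with a technique tag and quality flags."""

    def __init__(self, items, technique: str | None = None, flags: frozenset = frozenset()):
        super().__init__(items)
        self.technique = technique
        self.flags = frozenset(flags)


@dataclass(frozen=True)
class QuantizedImage:
    levels: np.ndarray  # integer gray levels in 1..n_levels
    n_levels: int

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValidationError("n_levels must be >= 2")
        lv = self.levels
        if lv.ndim != 2 or lv.size == 0:
            raise ValidationError("levels must be a nonempty 2D array")
        if lv.min() < 1 or lv.max() > self.n_levels:
            raise ValidationError("levels must lie in 1..n_levels")


@dataclass(frozen=True)
class CooccurrenceMatrix:
    P: np.ndarray  # n_levels x n_levels, sums to 1
    offset: tuple[int, int]
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float


@dataclass(frozen=True)
class RunLengthMatrix:
    P: np.ndarray  # n_levels x max_run_length run counts
    direction: int
    n_runs: int
    n_pixels: int


@dataclass(frozen=True)
class DifferenceHistogram:
    P: np.ndarray  # histogram over differences 0..n_levels-1, sums to 1
    displacement: tuple[int, int]


def quantize(img, n_levels: int = 8, allow_constant: bool = False) -> QuantizedImage:
    """Uniformly bin [min, max] into ``n_levels`` levels labeled 1..n_levels.

    The minimum maps to level 1 and the maximum to level n_levels. Constant
    images are refused unless ``allow_constant`` (then all pixels get level
    1) — a constant SLT subband is a legitimate input downstream.
    """
    a = _as_image(img)
    if n_levels < 2:
        raise ValidationError(f"n_levels must be >= 2, got {n_levels}")
    lo, hi = a.min(), a.max()
    if hi <= lo:
        if not allow_constant:
            raise ValidationError("cannot quantize a constant image")
        return QuantizedImage(np.ones(a.shape, dtype=np.int64), n_levels)
    lv = 1 + np.floor((a - lo) / (hi - lo) * n_levels).astype(np.int64)
    np.clip(lv, 1, n_levels, out=lv)
    return QuantizedImage(lv, n_levels)


# ---------------------------------------------------------------- GLCM


def compute_glcm(q: QuantizedImage, offset: tuple[int, int] = (0, 1)) -> CooccurrenceMatrix:
    """Directional co-occurrence matrix for one displacement ``(dr, dc)``.

    Counts ordered pairs (level at p, level at p + offset) over every
    position where both pixels exist, normalized to sum 1.
    """
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ValidationError("offset must be nonzero")
    lv = q.levels
    h, w = lv.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r0 >= r1 or c0 >= c1:
        raise ValidationError(f"no valid pixel pairs for offset {offset} on shape {lv.shape}")
    src = lv[r0:r1, c0:c1].ravel()
    dst = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    n = q.n_levels
    counts = np.zeros((n, n))
    np.add.at(counts, (src - 1, dst - 1), 1.0)
    P = counts / counts.sum()
    i = np.arange(1, n + 1, dtype=float)
    px, py = P.sum(axis=1), P.sum(axis=0)
    mu_x, mu_y = float(i @ px), float(i @ py)
    sigma_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((i - mu_y) ** 2) @ py))
    return CooccurrenceMatrix(P=P, offset=(dr, dc), mu_x=mu_x, mu_y=mu_y,
                              sigma_x=sigma_x, sigma_y=sigma_y)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def glcm_features(C: CooccurrenceMatrix) -> FeatureVector:
    """The ten co-occurrence features.

    Correlation with a zero marginal standard deviation is reported as 0
    and flagged ``degenerate_correlation`` instead of propagating NaN.
    """
    P = C.P
    n = P.shape[0]
    i, j = np.meshgrid(np.arange(1, n + 1, dtype=float),
                       np.arange(1, n + 1, dtype=float), indexing="ij")
    d = i - j
    flags = set()
    if C.sigma_x == 0 or C.sigma_y == 0:
        cor = 0.0
        flags.add("degenerate_correlation")
    else:
        cor = float((((i * j) * P).sum() - C.mu_x * C.mu_y) / (C.sigma_x * C.sigma_y))
    vals = {
        "hom": float((P / (1.0 + d**2)).sum()),
        "enr": float((P**2).sum()),
        "ent": _entropy(P),
        "sym": float(np.abs(P - P.T).sum()),
        "con": float((d**2 * P).sum()),
        "cor": cor,
        "mom1": float((d * P).sum()),
        "mom2": float((d**2 * P).sum()),
        "mom3": float((d**3 * P).sum()),
        "mom4": float((d**4 * P).sum()),
    }
    return FeatureVector(vals, technique="glcm", flags=flags)


def glcm_feature_set(q: QuantizedImage, offsets=GLCM_OFFSETS) -> FeatureVector:
    """Features averaged over the four distance-1 directions (rotation
    robustness; standard texture-analysis practice)."""
    per = [glcm_features(compute_glcm(q, off)) for off in offsets]
    return _average(per)


# ---------------------------------------------------------------- GLRLM


def _direction_lines(lv: np.ndarray, direction: int) -> list[np.ndarray]:
    h, w = lv.shape
    if direction == 0:
        return list(lv)
    if direction == 90:
        return list(lv.T)
    if direction == 45:
        flipped = np.fliplr(lv)
        return [np.diagonal(flipped, k) for k in range(-(h - 1), w)]
    if direction == 135:
        return [np.diagonal(lv, k) for k in range(-(h - 1), w)]
    raise ValidationError(f"direction must be one of {GLRLM_DIRECTIONS}, got {direction}")


def compute_glrlm(q: QuantizedImage, direction: int = 0) -> RunLengthMatrix:
    """Maximal-run counts by gray level and run length along a direction."""
    lv = q.levels
    lines = _direction_lines(lv, direction)
    # concatenate lines with a separator so run detection is one vector pass
    sep = 0  # levels are >= 1
    joined = np.concatenate([np.append(line, sep) for line in lines])
    boundaries = np.flatnonzero(np.diff(joined) != 0)
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [len(joined)]))
    values = joined[starts]
    lengths = ends - starts
    keep = values != sep
    values, lengths = values[keep], lengths[keep]
    max_len = max(lv.shape)
    P = np.zeros((q.n_levels, max_len))
    np.add.at(P, (values - 1, lengths - 1), 1.0)
    return RunLengthMatrix(P=P, direction=direction, n_runs=int(P.sum()),
                           n_pixels=int(lv.size))


def glrlm_features(R: RunLengthMatrix) -> FeatureVector:
    """The seven run-length features (gray levels and lengths 1-indexed)."""
    if R.n_runs < 1:
        raise ValidationError("run-length matrix holds no runs")
    P = R.P
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    nr = R.n_runs
    vals = {
        "sre": float((P / j**2).sum() / nr),
        "lre": float((P * j**2).sum() / nr),
        "gln": float((P.sum(axis=1) ** 2).sum() / nr),
        "rp": nr / R.n_pixels,
        "rln": float((P.sum(axis=0) ** 2).sum() / nr),
        "lgre": float((P / i**2).sum() / nr),
        "hgre": float((P * i**2).sum() / nr),
    }
    return FeatureVector(vals, technique="glrlm")


def glrlm_feature_set(q: QuantizedImage, directions=GLRLM_DIRECTIONS) -> FeatureVector:
    """Run-length features averaged over the four directions."""
    per = [glrlm_features(compute_glrlm(q, d)) for d in directions]
    return _average(per)


# ---------------------------------------------------------------- GLDS


def compute_glds(q: QuantizedImage, displacement: tuple[int, int] = (1, 1)) -> DifferenceHistogram:
    """Normalized histogram of |level(p) - level(p + d)| over valid p."""
    dx, dy = displacement
    if dx == 0 and dy == 0:
        raise ValidationError("displacement must be nonzero")
    lv = q.levels
    h, w = lv.shape
    r0, r1 = max(0, -dx), h - max(0, dx)
    c0, c1 = max(0, -dy), w - max(0, dy)
    if r0 >= r1 or c0 >= c1:
        raise ValidationError(f"no valid positions for displacement {displacement}")
    diff = np.abs(lv[r0:r1, c0:c1] - lv[r0 + dx : r1 + dx, c0 + dy : c1 + dy]).ravel()
    counts = np.bincount(diff, minlength=q.n_levels).astype(float)[: q.n_levels]
    return DifferenceHistogram(P=counts / counts.sum(), displacement=(dx, dy))


def glds_features(H: DifferenceHistogram) -> FeatureVector:
    """The four difference-statistics features over differences g = 0..N-1."""
    P = H.P
    g = np.arange(len(P), dtype=float)
    vals = {
        "asm": float((P**2).sum()),
        "con": float((g**2 * P).sum()),
        "men": float((g * P).sum()),
        "ent": _entropy(P),
    }
    return FeatureVector(vals, technique="glds")


# ------------------------------------------------------- aggregation


def _combine(vectors, weight: float) -> FeatureVector:
    first = vectors[0]
    keys = list(first.keys())
    for v in vectors[1:]:
        if list(v.keys()) != keys:
            raise SchemaError(f"feature name sets differ: {keys} vs {list(v.keys())}")
    out = {k: weight * sum(v[k] for v in vectors) for k in keys}
    flags = frozenset().union(*(v.flags if isinstance(v, FeatureVector) else frozenset()
                                for v in vectors))
    tech = first.technique if isinstance(first, FeatureVector) else None
    return FeatureVector(out, technique=tech, flags=flags)


def _average(vectors) -> FeatureVector:
    return _combine(vectors, 1.0 / len(vectors))


def aggregate_ns(fT: FeatureVector, fI: FeatureVector, fF: FeatureVector) -> FeatureVector:
    """Neutrosophic aggregation: the elementwise T + I + F sum of one
    feature computed per membership map."""
    return _combine([fT, fI, fF], 1.0)
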