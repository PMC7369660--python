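"""Feature-extraction scenarios composing the preprocessing, neutrosophic,
Slantlet, and texture stages.

Four scenarios are exposed:

* ``spatial`` — texture features on the (quantized) raw image; baseline.
* ``ns``      — features per T/I/F membership map, summed.
* ``slt``     — features on the 2D Slantlet coefficient array of the image.
* ``ns-slt``  — the composite: SLT of each membership map, features per
  channel, summed.

The SLT coefficient array is treated as one image: optionally thresholded
(relative eps), affinely rescaled to [0, 1], then quantized before matrix
computation (the quantizer needs a bounded range). Images whose dimensions
are not multiples of 2^l are reflection-padded up to the next multiple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import NSLTError, ValidationError
from .neutrosophic import to_neutrosophic
from .preprocess import standardize, _as_image
from .slantlet import slt2d_forward, suppress_small_coefficients
from . import texture
from .texture import (
    FeatureVector,
    GLCM_OFFSETS,
    GLRLM_DIRECTIONS,
    aggregate_ns,
    quantize,
)

__all__ = ["ScenarioConfig", "extract_features", "extract_dataset", "SCENARIOS", "TECHNIQUES"]

log = logging.getLogger(__name__)

SCENARIOS = ("spatial", "ns", "slt", "ns-slt")
TECHNIQUES = ("glcm", "glrlm", "glds")
_PREFIX = {"spatial": "", "ns": "ns_", "slt": "slt_", "ns-slt": "nsslt_"}


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that determines a feature vector for one image."""

    scenario: str = "ns-slt"
    techniques: tuple[str, ...] = TECHNIQUES  # Table-1 concatenation order
    ns_window: int = 5
    slt_scales: int = 2
    levels: int = 8
    glcm_offsets: tuple[tuple[int, int], ...] = GLCM_OFFSETS
    glrlm_directions: tuple[int, ...] = GLRLM_DIRECTIONS
    glds_displacement: tuple[int, int] = (1, 1)
    slt_eps: float = 0.0
    preprocess: bool = False
    resize_side: int = 512
    background_level: float = 0.0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if not self.techniques:
            raise ValidationError("at least one technique is required")
        for t in self.techniques:
            if t not in TECHNIQUES:
                raise ValidationError(f"unknown technique {t!r}")
        if self.levels < 2:
            raise ValidationError("levels must be >= 2")
        if self.slt_scales < 1:
            raise ValidationError("slt_scales must be >= 1")
        if self.slt_eps < 0:
            raise ValidationError("slt_eps must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _pad_to_multiple(a: np.ndarray, block: int) -> np.ndarray:
    h, w = a.shape
    ph = (-h) % block
    pw = (-w) % block
    if ph == 0 and pw == 0:
        return a
    return np.pad(a, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)), mode="symmetric")


def _rescale_unit(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def _slt_image(map2d: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    """SLT coefficient array of one map, thresholded and rescaled to [0,1]."""
    padded = _pad_to_multiple(map2d, 2**cfg.slt_scales)
    coeffs = slt2d_forward(padded, cfg.slt_scales)
    if cfg.slt_eps > 0:
        coeffs = suppress_small_coefficients(coeffs, cfg.slt_eps)
    return _rescale_unit(coeffs.array)


def _map_features(map2d: np.ndarray, cfg: ScenarioConfig) -> FeatureVector:
    """Concatenated technique features for a single 2D map."""
    q = quantize(map2d, cfg.levels, allow_constant=True)
    out: dict[str, float] = {}
    flags: set[str] = set()
    for tech in cfg.techniques:
        if tech == "glcm":
            fv = texture.glcm_feature_set(q, cfg.glcm_offsets)
        elif tech == "glrlm":
            fv = texture.glrlm_feature_set(q, cfg.glrlm_directions)
        else:
            fv = texture.glds_features(texture.compute_glds(q, cfg.glds_displacement))
        out.update({f"{tech}_{k}": v for k, v in fv.items()})
        flags |= set(fv.flags)
    return FeatureVector(out, technique="+".join(cfg.techniques), flags=flags)


def _scenario_maps(img: np.ndarray, cfg: ScenarioConfig) -> list[np.ndarray]:
    if cfg.scenario == "spatial":
        return [img]
    if cfg.scenario == "ns":
        ns = to_neutrosophic(img, cfg.ns_window)
        return [ns.T, ns.I, ns.F]
    if cfg.scenario == "slt":
        return [_slt_image(img, cfg)]
    ns = to_neutrosophic(img, cfg.ns_window)
    return [_slt_image(m, cfg) for m in (ns.T, ns.I, ns.F)]


def extract_features(img, cfg: ScenarioConfig) -> FeatureVector:
    """One named feature vector for one image under a scenario.

    Multi-map scenarios (ns, ns-slt) aggregate by the elementwise sum over
    the three membership channels; keys carry the scenario prefix and the
    Table-1 concatenation order glcm | glrlm | glds.
    """
    a = _as_image(img)
    if cfg.preprocess:
        a = standardize(a, cfg.resize_side, cfg.background_level)
    maps = _scenario_maps(a, cfg)
    per_map = [_map_features(m, cfg) for m in maps]
    fv = per_map[0] if len(per_map) == 1 else aggregate_ns(*per_map)
    prefix = _PREFIX[cfg.scenario]
    return FeatureVector({f"{prefix}{k}": v for k, v in fv.items()},
                         technique=fv.technique, flags=fv.flags)


def extract_dataset(images, labels, cfg: ScenarioConfig) -> pd.DataFrame:
    """Feature table (one row per image, ``label`` column last).

    Per-image failures are logged and the image skipped; if every image
    fails an empty-table error is raised. Row order equals input order of
    the successfully processed images, so extraction is deterministic.
    """
    images = list(images)
    labels = list(labels)
    if len(images) != len(labels):
        raise ValidationError("images and labels must have equal length")
    if len(images) < 2:
        raise ValidationError("need at least 2 images")
    rows, kept = [], []
    for idx, (img, lab) in enumerate(zip(images, labels)):
        try:
            rows.append(dict(extract_features(img, cfg)))
            kept.append(lab)
        except NSLTError as exc:
            log.warning("image %d skipped: %s", idx, exc)
    if not rows:
        raise ValidationError("feature extraction failed for every image: empty table")
    table = pd.DataFrame(rows)
    table["label"] = kept
    return table
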