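"""Image and table I/O.

Reads 8/16-bit grayscale PNG/TIFF and NIfTI volumes (with slice/axis
selection); integer intensities are rescaled by their dtype maximum and
floating inputs min-max rescaled into [0, 1] when they fall outside it.
Feature tables round-trip losslessly through CSV (pandas writes
shortest-round-trip float representations).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .pipeline import ScenarioConfig

__all__ = ["read_image", "write_image", "write_feature_table", "read_feature_table",
           "read_manifest", "RunConfig"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _NIFTI_SUFFIXES)


def _rescale(a: np.ndarray, dtype) -> np.ndarray:
    a = np.asarray(a)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return a.astype(float) / info.max
    a = a.astype(float)
    lo, hi = a.min(), a.max()
    if lo < 0 or hi > 1:
        if hi > lo:
            return (a - lo) / (hi - lo)
        return np.zeros_like(a)
    return a


def read_image(path, slice_index: int | None = None, axis: int = 2,
               to_gray: bool = False) -> np.ndarray:
    """Load a 2D grayscale image in [0, 1] from PNG/TIFF or NIfTI.

    For volumes, ``slice_index`` selects a plane along ``axis`` (default:
    the middle slice of the last axis — for axial MR stacks that is the
    slice most likely to show all tissue classes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 2:
            a = vol
        else:
            if vol.ndim != 3:
                raise ValidationError(f"expected 2D/3D NIfTI, got {vol.ndim}D")
            if not 0 <= axis < 3:
                raise ValidationError(f"axis must be 0..2, got {axis}")
            n = vol.shape[axis]
            idx = n // 2 if slice_index is None else slice_index
            if not 0 <= idx < n:
                raise ValidationError(f"slice {idx} out of range for axis {axis} (size {n})")
            a = np.take(vol, idx, axis=axis)
        return _rescale(a, a.dtype)
    suffix = path.suffix.lower()
    if suffix not in _IMAGE_SUFFIXES:
        raise ValidationError(f"unrecognized image format {suffix!r} ({path.name})")
    raw = iio.imread(path)
    if raw.ndim == 3:
        if not to_gray:
            raise ValidationError(f"{path.name} is not grayscale; pass to_gray=True")
        weights = np.array([0.2125, 0.7154, 0.0721])
        raw = (raw[..., :3].astype(float) * weights).sum(axis=-1).astype(raw.dtype)
    if raw.ndim != 2:
        raise ValidationError(f"expected a 2D image, got shape {raw.shape}")
    return _rescale(raw, raw.dtype)


def write_image(path, img: np.ndarray) -> None:
    """Save a [0, 1] float image as 16-bit PNG/TIFF."""
    a = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(a * np.iinfo(np.uint16).max).astype(np.uint16))


def write_feature_table(table: pd.DataFrame, path) -> None:
    """CSV with a header row, label column last; lossless for 15-digit reals."""
    if table.empty:
        raise ValidationError("refusing to write an empty feature table")
    cols = [c for c in table.columns if c != "label"] + (
        ["label"] if "label" in table.columns else [])
    table[cols].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path)


def read_manifest(path) -> tuple[list[np.ndarray], list[str]]:
    """Load images listed in a ``path,label`` manifest CSV (paths relative
    to the manifest's directory)."""
    path = Path(path)
    df = read_feature_table(path)
    if not {"path", "label"} <= set(df.columns):
        raise ValidationError("manifest must have 'path' and 'label' columns")
    images = [read_image(path.parent / p) for p in df["path"]]
    return images, list(df["label"].astype(str))


@dataclass(frozen=True)
class RunConfig:
    """Full-pipeline configuration, serializable to one JSON document."""

    scenario: ScenarioConfig = ScenarioConfig()
    select_k: int | None = 3
    classifiers: tuple[str, ...] = ("svm", "dt", "knn", "nb")
    folds: int = 10
    global_fit: bool = False
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["scenario"] = asdict(self.scenario)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "scenario" in d:
            sc = d["scenario"]
            sc_known = {f.name for f in fields(ScenarioConfig)}
            sc_unknown = set(sc) - sc_known
            if sc_unknown:
                raise ValidationError(f"unknown scenario keys: {sorted(sc_unknown)}")
            for key in ("techniques", "glrlm_directions"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            if "glcm_offsets" in sc:
                sc["glcm_offsets"] = tuple(tuple(o) for o in sc["glcm_offsets"])
            if "glds_displacement" in sc:
                sc["glds_displacement"] = tuple(sc["glds_displacement"])
            d["scenario"] = ScenarioConfig(**sc)
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        return cls(**d)
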