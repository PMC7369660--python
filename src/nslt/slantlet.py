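"""Slantlet transform (SLT): an orthogonal, non-iterated filter-bank
wavelet variant with piecewise-linear basis functions and two vanishing
moments.

For ``l`` scales the bank has ``2l`` channels:

* the coarse lowpass pair ``(h_l, f_l)`` — a constant and a centered linear
  "slant" over a block of ``2^l`` samples, each downsampled by ``2^l``;
* for every intermediate scale ``i = 1 .. l-1`` a slantlet ``g_i`` of
  support ``2^(i+1)`` together with its time-reverse, each downsampled by
  ``2^(i+1)``.

All supports tile the signal exactly, so the transform of a length-``n``
signal (``n`` a multiple of ``2^l``) is an ``n x n`` orthonormal matrix.

Filter construction
-------------------
Each ``g_i`` is linear on each half of its support and must satisfy: unit
norm, two vanishing moments (zero 0th and 1st moments, which also make it
orthogonal to every coarser basis function, all of which restrict to affine
functions on its support), and orthogonality to its own time-reverse. In
the 2-dimensional space W of half-linear vectors orthogonal to constants
and ramps, time reversal is an involution with one symmetric eigenvector u
and one antisymmetric eigenvector v; the unique unit solutions orthogonal
to their own reverse are (u ± v)/sqrt(2). Both u and v have closed forms,
so the bank is constructed analytically and verified by the Gram-identity
property tests. Signs are fixed so each filter's first nonzero tap is
positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .preprocess import _as_image

__all__ = [
    "SLTFilterBank",
    "SLTCoefficients",
    "build_filter_bank",
    "transform_matrix",
    "channel_layout",
    "slt2d_forward",
    "slt2d_inverse",
    "suppress_small_coefficients",
]


def _fix_sign(w: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(w) > 1e-14)
    return -w if len(nz) and w[nz[0]] < 0 else w


def _lowpass_pair(block: int) -> tuple[np.ndarray, np.ndarray]:
    """(h, f): orthonormal basis of the affine signals on one block."""
    n = np.arange(block, dtype=float)
    h = np.full(block, 1.0 / np.sqrt(block))
    f = n - (block - 1) / 2.0
    f /= np.linalg.norm(f)
    return _fix_sign(h), _fix_sign(f)


def _slantlet_filter(i: int) -> np.ndarray:
    """g_i of support 2^(i+1): half-linear, two vanishing moments,
    orthogonal to its own time-reverse."""
    m = 2**i
    n = np.arange(m, dtype=float)
    # symmetric element of W: centered ramp on the first half, mirrored
    u = np.concatenate([n - (m - 1) / 2.0, (n - (m - 1) / 2.0)[::-1]])
    u /= np.linalg.norm(u)
    # antisymmetric element of W: c + n on the first half, negated mirror;
    # c chosen so the full-support first moment vanishes
    c = -(m - 1) * (2 * m - 1) / (6.0 * m)
    v = np.concatenate([c + n, -(c + n)[::-1]])
    v /= np.linalg.norm(v)
    return _fix_sign((u + v) / np.sqrt(2.0))


@dataclass(frozen=True)
class SLTFilterBank:
    """The 2l-channel Slantlet analysis bank for ``scales = l``."""

    scales: int
    lowpass: np.ndarray  # h_l, support 2^l, downsample 2^l
    slant: np.ndarray  # f_l, support 2^l, downsample 2^l
    slantlets: dict[int, np.ndarray]  # i -> g_i, support 2^(i+1), downsample 2^(i+1)

    @property
    def n_channels(self) -> int:
        return 2 * self.scales

    @property
    def block(self) -> int:
        return 2**self.scales

    def channels(self) -> list[tuple[str, np.ndarray, int]]:
        """(name, taps, downsampling) per channel, coarse to fine."""
        out = [("h", self.lowpass, self.block), ("f", self.slant, self.block)]
        for i in sorted(self.slantlets, reverse=True):
            g = self.slantlets[i]
            out.append((f"g{i}", g, 2 ** (i + 1)))
            out.append((f"g{i}r", g[::-1].copy(), 2 ** (i + 1)))
        return out

    def piecewise_params(self, taps: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
        """(intercept, slope) of each linear half of a filter's support."""
        half = len(taps) // 2
        out = []
        for seg, n0 in ((taps[:half], 0), (taps[half:], half)):
            if len(seg) == 1:
                out.append((float(seg[0]), 0.0))
            else:
                slope = float(seg[1] - seg[0])
                out.append((float(seg[0]) - slope * n0, slope))
        return tuple(out)  # type: ignore[return-value]


def build_filter_bank(l: int) -> SLTFilterBank:
    """Construct the l-scale Slantlet filter bank (l >= 1)."""
    if l < 1:
        raise ValidationError(f"scale count must be >= 1, got {l}")
    h, f = _lowpass_pair(2**l)
    gs = {i: _slantlet_filter(i) for i in range(1, l)}
    return SLTFilterBank(scales=l, lowpass=h, slant=f, slantlets=gs)


def _check_length(bank: SLTFilterBank, n: int) -> None:
    if n < bank.block or n % bank.block:
        raise ValidationError(
            f"signal length {n} must be a positive multiple of 2^l = {bank.block}"
        )


def channel_layout(bank: SLTFilterBank, n: int) -> dict[str, slice]:
    """Row ranges of each channel's coefficients in the transform output."""
    _check_length(bank, n)
    layout, row = {}, 0
    for name, _taps, step in bank.channels():
        count = n // step
        layout[name] = slice(row, row + count)
        row += count
    return layout


def transform_matrix(bank: SLTFilterBank, n: int) -> np.ndarray:
    """The n x n orthonormal SLT matrix; rows are shifted basis vectors."""
    _check_length(bank, n)
    G = np.zeros((n, n))
    row = 0
    for _name, taps, step in bank.channels():
        for shift in range(0, n, step):
            G[row, shift : shift + len(taps)] = taps
            row += 1
    return G


@dataclass(frozen=True)
class SLTCoefficients:
    """2D SLT coefficient array with its subband partition.

    ``array[row_layout[a], col_layout[b]]`` is the (a, b) subband; the
    approximation (LL) subband is ``("h", "h")`` and the remaining blocks
    are the detail subbands. The partition is disjoint and exhaustive, so
    the coefficient count equals the input pixel count.
    """

    array: np.ndarray
    bank: SLTFilterBank
    row_layout: dict[str, slice]
    col_layout: dict[str, slice]

    @property
    def shape(self):
        return self.array.shape

    def subband(self, row_channel: str, col_channel: str) -> np.ndarray:
        try:
            return self.array[self.row_layout[row_channel], self.col_layout[col_channel]]
        except KeyError as exc:
            raise ValidationError(f"unknown subband channel {exc}") from exc

    @property
    def ll(self) -> np.ndarray:
        """Approximation subband (lowpass in both directions)."""
        return self.subband("h", "h")

    def subband_index(self) -> dict[str, dict[str, list[int]]]:
        """JSON-friendly subband partition (start/stop per channel)."""
        return {
            "rows": {k: [s.start, s.stop] for k, s in self.row_layout.items()},
            "cols": {k: [s.start, s.stop] for k, s in self.col_layout.items()},
        }


def slt2d_forward(img, l: int = 2) -> SLTCoefficients:
    """Separable 2D SLT: transform columns then rows of the image.

    Both image dimensions must be multiples of 2^l. Orthonormality gives
    Parseval energy preservation and an exact inverse.
    """
    a = _as_image(img)
    bank = build_filter_bank(l)
    h, w = a.shape
    Gh = transform_matrix(bank, h)
    Gw = Gh if w == h else transform_matrix(bank, w)
    coeffs = Gh @ a @ Gw.T
    return SLTCoefficients(
        array=coeffs,
        bank=bank,
        row_layout=channel_layout(bank, h),
        col_layout=channel_layout(bank, w),
    )


def slt2d_inverse(coeffs: SLTCoefficients) -> np.ndarray:
    """Exact left-inverse of :func:`slt2d_forward`."""
    if not isinstance(coeffs, SLTCoefficients):
        raise ValidationError("expected SLTCoefficients")
    h, w = coeffs.array.shape
    expected_rows = {k: s for k, s in channel_layout(coeffs.bank, h).items()}
    if expected_rows != coeffs.row_layout:
        raise ValidationError("malformed subband layout")
    Gh = transform_matrix(coeffs.bank, h)
    Gw = Gh if w == h else transform_matrix(coeffs.bank, w)
    return Gh.T @ coeffs.array @ Gw


def suppress_small_coefficients(coeffs: SLTCoefficients, eps: float) -> SLTCoefficients:
    """Zero coefficients with |c| < eps * max|c|; others pass unchanged.

    ``eps = 0`` is the identity. Small SLT coefficients carry noise rather
    than structure, so discarding them before texture statistics is an
    optional cleanup step.
    """
    if eps < 0:
        raise ValidationError(f"suppression threshold must be >= 0, got {eps}")
    a = coeffs.array
    if eps == 0 or a.size == 0:
        out = a.copy()
    else:
        cut = eps * np.abs(a).max()
        out = np.where(np.abs(a) < cut, 0.0, a)
    return SLTCoefficients(
        array=out,
        bank=coeffs.bank,
        row_layout=coeffs.row_layout,
        col_layout=coeffs.col_layout,
    )
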