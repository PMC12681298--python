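"""Orthonormal separable Haar wavelet transform in N dimensions.

Hand-rolled because no wavelet library is assumed at runtime.  The transform
is strictly orthonormal (Parseval holds, inverse is exact) on extents
divisible by ``2**levels``; callers pad otherwise.  Coefficients are packed
in-place, approximation in the low-index corner (wavedec-style).
"""

from __future__ import annotations

import numpy as np

__all__ = ["haar_forward", "haar_inverse", "max_levels", "pad_to_levels"]

_SQRT2 = np.sqrt(2.0)


def max_levels(shape: tuple[int, ...]) -> int:
    """Largest level count so every axis stays even at every level."""
    lv = 0
    sizes = list(shape)
    while all(s % 2 == 0 and s >= 2 for s in sizes):
        lv += 1
        sizes = [s // 2 for s in sizes]
    return lv


def pad_to_levels(shape: tuple[int, ...], levels: int) -> tuple[int, ...]:
    """Smallest extents >= shape divisible by 2**levels."""
    m = 2**levels
    return tuple(int(np.ceil(s / m)) * m for s in shape)


def _step_axis(x: np.ndarray, axis: int, n: int) -> None:
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, n)
    seg = x[tuple(sl)]
    even = np.take(seg, np.arange(0, n, 2), axis=axis)
    odd = np.take(seg, np.arange(1, n, 2), axis=axis)
    a = (even + odd) / _SQRT2
    d = (even - odd) / _SQRT2
    x[tuple(sl)] = np.concatenate([a, d], axis=axis)


def _istep_axis(x: np.ndarray, axis: int, n: int) -> None:
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(0, n)
    seg = x[tuple(sl)]
    h = n // 2
    a = np.take(seg, np.arange(h), axis=axis)
    d = np.take(seg, np.arange(h, n), axis=axis)
    even = (a + d) / _SQRT2
    odd = (a - d) / _SQRT2
    out = np.empty_like(seg)
    slo = [slice(None)] * x.ndim
    sle = list(slo)
    sle[axis] = slice(0, n, 2)
    out[tuple(sle)] = even
    slo[axis] = slice(1, n, 2)
    out[tuple(slo)] = odd
    x[tuple(sl)] = out


def haar_forward(x: np.ndarray, levels: int) -> np.ndarray:
    """Multi-level orthonormal Haar DWT along every axis."""
    ns = list(x.shape)
    if any(s % (2**levels) for s in ns):
        raise ValueError(f"shape {x.shape} not divisible by 2**{levels}")
    y = np.array(x, copy=True)
    for _ in range(levels):
        corner = y[tuple(slice(0, n) for n in ns)]
        for ax in range(y.ndim):
            _step_axis(corner, ax, ns[ax])
        ns = [n // 2 for n in ns]
    return y


def haar_inverse(y: np.ndarray, levels: int) -> np.ndarray:
    x = np.array(y, copy=True)
    ns = [s // 2 ** (levels - 1) for s in x.shape]
    for _ in range(levels):
        corner = x[tuple(slice(0, n) for n in ns)]
        for ax in reversed(range(x.ndim)):
            _istep_axis(corner, ax, ns[ax])
        ns = [min(n * 2, s) for n, s in zip(ns, x.shape)]
    return x
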