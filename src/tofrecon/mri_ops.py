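"""Linear MRI operators and classical reconstruction baselines.

Conventions (used consistently across the package):

* Fourier transforms are centered (DC at the array center) and unitary
  (``norm="ortho"``), so Parseval identities are exact.
* Multi-coil k-space arrays carry the coil axis FIRST: ``(n_coils, nx, ny, nz)``
  with the readout along the first spatial axis.
* Coil sensitivity stacks are SoS-normalized: ``sum_i |S_i|**2 == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import wavelet
from .errors import InvalidConfigError, ShapeError, StepSizeError

__all__ = [
    "fft3c",
    "ifft3c",
    "fftnc",
    "ifftnc",
    "rss",
    "sens_expand",
    "sens_reduce",
    "coil_compress_svd",
    "crop_center_kspace",
    "zero_fill_recon",
    "CSConfig",
    "cs_l1wavelet_recon",
    "readout_decouple",
]


def fftnc(x: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Centered unitary FFT over ``axes``."""
    x = np.fft.ifftshift(x, axes=axes)
    x = np.fft.fftn(x, axes=axes, norm="ortho")
    return np.fft.fftshift(x, axes=axes)


def ifftnc(x: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Centered unitary inverse FFT over ``axes``."""
    x = np.fft.ifftshift(x, axes=axes)
    x = np.fft.ifftn(x, axes=axes, norm="ortho")
    return np.fft.fftshift(x, axes=axes)


def fft3c(image: np.ndarray) -> np.ndarray:
    """Centered unitary 3D FFT over the last three axes."""
    return fftnc(np.asarray(image, dtype=complex), axes=(-3, -2, -1))


def ifft3c(kspace: np.ndarray) -> np.ndarray:
    """Centered unitary 3D inverse FFT over the last three axes."""
    return ifftnc(np.asarray(kspace, dtype=complex), axes=(-3, -2, -1))


def rss(coil_images: np.ndarray, axis: int = 0) -> np.ndarray:
    """Root-sum-of-squares coil combination."""
    return np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=axis))


def _spatial_axes(ndim_spatial: int) -> tuple[int, ...]:
    return tuple(range(-ndim_spatial, 0))


def sens_expand(image: np.ndarray, coils: np.ndarray) -> np.ndarray:
    """Expand a coil-combined image to per-coil k-space: ``F{S_i * m}``."""
    if image.shape != coils.shape[1:]:
        raise ShapeError(f"image {image.shape} vs coils {coils.shape}")
    return fftnc(coils * image[None], axes=_spatial_axes(image.ndim))

def sens_reduce(kspace: np.ndarray, coils: np.ndarray) -> np.ndarray:
    """Combine per-coil k-space into one image: ``sum_i conj(S_i) F^-1{k_i}``."""
    if kspace.shape != coils.shape:
        raise ShapeError(f"kspace {kspace.shape} vs coils {coils.shape}")
    imgs = ifftnc(kspace, axes=_spatial_axes(kspace.ndim - 1))
    return np.sum(np.conj(coils) * imgs, axis=0)


def coil_compress_svd(kspace: np.ndarray, n_virtual: int = 8) -> tuple[np.ndarray, float]:
    """SVD coil compression onto ``n_virtual`` virtual coils.

    Returns ``(compressed_kspace, energy_retained)`` where the energy is the
    fraction of squared singular values kept.
    """
    n_coils = kspace.shape[0]
    if n_virtual > n_coils:
        raise InvalidConfigError(f"n_virtual={n_virtual} > n_coils={n_coils}")
    mat = kspace.reshape(n_coils, -1)  # coils x samples
    # right singular vectors of samples x coils == left of coils x samples^H
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    proj = u[:, :n_virtual]  # (n_coils, n_virtual)
    comp = (proj.conj().T @ mat).reshape((n_virtual,) + kspace.shape[1:])
    tot = float(np.sum(s**2))
    energy = float(np.sum(s[:n_virtual] ** 2) / tot) if tot > 0 else 1.0
    return comp, energy


def crop_center_kspace(kspace: np.ndarray, target: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Symmetric center crop of the in-plane k-space axes (1 and 2 of the
    spatial axes); readout and coil axes untouched."""
    ny, nz = kspace.shape[-2], kspace.shape[-1]
    ty, tz = target
    if ty > ny or tz > nz:
        raise InvalidConfigError(f"crop target {target} exceeds extent {(ny, nz)}")
    oy, oz = (ny - ty) // 2, (nz - tz) // 2
    return kspace[..., oy : oy + ty, oz : oz + tz]


def zero_fill_recon(kspace: np.ndarray, coils: np.ndarray | None = None) -> np.ndarray:
    """Inverse transform of (masked) k-space followed by coil combination.

    RSS when no maps are given; conjugate-map combination otherwise.
    """
    imgs = ifftnc(kspace, axes=_spatial_axes(kspace.ndim - 1))
    if coils is None:
        return rss(imgs)
    if coils.shape != kspace.shape:
        raise ShapeError(f"coils {coils.shape} vs kspace {kspace.shape}")
    return np.abs(np.sum(np.conj(coils) * imgs, axis=0))


@dataclass
class CSConfig:
    """L1-wavelet FISTA settings. ``lam`` is relative to the maximum
    zero-filled intensity."""

    lam: float = 0.005
    n_iters: int = 60
    wavelet_levels: int = 4
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iters < 1:
            raise InvalidConfigError("n_iters must be >= 1")
        if self.lam < 0:
            raise InvalidConfigError("lambda must be >= 0")
        if self.step <= 0:
            raise InvalidConfigError("step must be > 0")


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    mag = np.abs(x)
    scale = np.maximum(mag - t, 0.0) / np.maximum(mag, 1e-30)
    return x * scale


def _wavelet_prox(m: np.ndarray, t: float, levels: int) -> np.ndarray:
    lv = min(levels, wavelet.max_levels(m.shape))
    if lv == 0:
        return _soft(m, t)
    padded_shape = wavelet.pad_to_levels(m.shape, lv)
    if padded_shape != m.shape:
        pad = [(0, p - s) for p, s in zip(padded_shape, m.shape)]
        mp = np.pad(m, pad)
    else:
        mp = m
    coef = wavelet.haar_forward(mp, lv)
    coef = _soft(coef, t)
    out = wavelet.haar_inverse(coef, lv)
    return out[tuple(slice(0, s) for s in m.shape)]


def _wavelet_l1(m: np.ndarray, levels: int) -> float:
    lv = min(levels, wavelet.max_levels(m.shape))
    if lv == 0:
        return float(np.sum(np.abs(m)))
    padded_shape = wavelet.pad_to_levels(m.shape, lv)
    if padded_shape != m.shape:
        pad = [(0, p - s) for p, s in zip(padded_shape, m.shape)]
        m = np.pad(m, pad)
    return float(np.sum(np.abs(wavelet.haar_forward(m, lv))))


def cs_l1wavelet_recon(
    kspace: np.ndarray,
    mask: np.ndarray,
    coils: np.ndarray,
    cfg: CSConfig | None = None,
    return_objectives: bool = False,
):
    """L1-wavelet regularized CS reconstruction by monotone (restarted) FISTA.

    Solves ``min_m 0.5 ||M F S m - y||^2 + lam ||Psi m||_1`` and returns the
    magnitude of the solution (optionally with the objective trace).
    """
    cfg = cfg or CSConfig()
    mask = np.asarray(mask)
    maskf = mask.astype(float)
    y = kspace * maskf  # defensive: operate on the measured samples only
    m0 = sens_reduce(y, coils)
    lam_abs = cfg.lam * float(np.abs(m0).max() + 1e-30)

    def grad(m):
        r = maskf * sens_expand(m, coils) - y
        return sens_reduce(maskf * r, coils)

    def objective(m):
        r = maskf * sens_expand(m, coils) - y
        return 0.5 * float(np.sum(np.abs(r) ** 2)) + lam_abs * _wavelet_l1(m, cfg.wavelet_levels)

    t_step = cfg.step  # ||M F S||^2 <= 1 for SoS-normalized coils
    m = m0.copy()
    z = m.copy()
    tk = 1.0
    objs = [objective(m)]
    bad_restarts = 0
    for _ in range(cfg.n_iters):
        m_new = _wavelet_prox(z - t_step * grad(z), t_step * lam_abs, cfg.wavelet_levels)
        obj_new = objective(m_new)
        if obj_new > objs[-1] + 1e-12 * max(1.0, abs(objs[-1])):
            # restart momentum from the last good iterate
            bad_restarts += 1
            if bad_restarts >= 5:
                raise StepSizeError(
                    f"objective increased over {bad_restarts} consecutive restarts; reduce step"
                )
            z = m.copy()
            tk = 1.0
            m_new = _wavelet_prox(z - t_step * grad(z), t_step * lam_abs, cfg.wavelet_levels)
            obj_new = objective(m_new)
            if obj_new > objs[-1] + 1e-12 * max(1.0, abs(objs[-1])):
                m_new, obj_new = m, objs[-1]
        else:
            bad_restarts = 0
        tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk**2))
        z = m_new + ((tk - 1.0) / tk_new) * (m_new - m)
        m, tk = m_new, tk_new
        objs.append(obj_new)
    out = np.abs(m)
    if return_objectives:
        return out, objs
    return out


def readout_decouple(kspace: np.ndarray) -> np.ndarray:
    """Inverse Fourier transform along the readout (first spatial) axis,
    producing a stack of 2D ky-kz k-space planes (hybrid space), as used by
    slicewise 2D baselines."""
    return ifftnc(kspace, axes=(-3,))
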