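"""The unrolled 3D variational network with partial-Fourier-aware data
consistency.

Structure: a sensitivity-estimation U-Net fed by the calibration region,
followed by ``n_cascades`` unrolled steps; each step combines coils,
refines the complex image with a U-Net, re-projects to k-space and applies
data consistency.  Hard DC pins every acquired sample (including the whole
asymmetric partial-Fourier band policy: the unacquired band passes through
untouched for the network to fill).  Down/up-sampling is anisotropic: the
thin slice axis is pooled only at the first ``pool_levels_slice`` encoder
levels.

Forward and backward are both explicit; gradients are exact (checked by
finite differences in the tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..errors import CalibrationError, InvalidConfigError, ShapeError
from ..ksim import CoilSensitivities, SamplingMask
from ..mri_ops import fftnc, ifftnc
from . import nn

__all__ = [
    "VarNetConfig",
    "VarNetModel",
    "CascadeState",
    "build_model",
    "count_parameters",
    "estimate_sensitivities",
    "dc_step",
    "reconstruct",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class VarNetConfig:
    """Architecture hyperparameters.

    The defaults reproduce the published layer widths: 12 cascades with
    refinement U-Nets of base width 18 (4 pooling levels) and a sensitivity
    U-Net of base width 8; ``dimensionality="2D"`` gives the 29.9M-parameter
    baseline and ``"3D"`` with 4/4/2 pooling the 84.6M-parameter variant.
    """

    n_cascades: int = 12
    chans: int = 18
    sens_chans: int = 8
    pool_levels_inplane: int = 4
    pool_levels_slice: int = 2
    dimensionality: str = "3D"
    dc_mode: str = "hard"

    def __post_init__(self) -> None:
        if self.dimensionality not in ("2D", "3D"):
            raise InvalidConfigError("dimensionality must be '2D' or '3D'")
        if self.dc_mode not in ("hard", "soft"):
            raise InvalidConfigError("dc_mode must be 'hard' or 'soft'")
        if self.pool_levels_slice > self.pool_levels_inplane:
            raise InvalidConfigError("pool_levels_slice must be <= pool_levels_inplane")
        if self.n_cascades < 1 or self.chans < 1 or self.sens_chans < 1:
            raise InvalidConfigError("cascades and channel widths must be >= 1")

    @property
    def ndim(self) -> int:
        return 2 if self.dimensionality == "2D" else 3

    def strides(self) -> list[tuple[int, ...]]:
        """Per-level pooling strides; the slice axis (last) is pooled only at
        the first ``pool_levels_slice`` levels."""
        out = []
        for lv in range(self.pool_levels_inplane):
            if self.ndim == 2:
                out.append((2, 2))
            else:
                out.append((2, 2, 2 if lv < self.pool_levels_slice else 1))
        return out


@dataclass
class CascadeState:
    """One unrolled iterate: current k-space, the measured reference and the
    sampling mask."""

    current_kspace: np.ndarray
    reference_kspace: np.ndarray
    mask: SamplingMask

    def __post_init__(self) -> None:
        if self.current_kspace.shape != self.reference_kspace.shape:
            raise ShapeError("current and reference k-space shapes differ")

    def sampled_pattern(self) -> np.ndarray:
        """Boolean acquired-sample pattern (pe and pf combined), broadcast to
        the spatial shape."""
        return _sampled_pattern(self.mask, self.current_kspace.shape[1:])


def _sampled_pattern(mask: SamplingMask, spatial_shape: tuple[int, ...]) -> np.ndarray:
    if len(spatial_shape) == 3:
        pat = mask.combined()
        if pat.shape != spatial_shape:
            raise ShapeError(f"mask {pat.shape} vs k-space {spatial_shape}")
    else:  # 2D: ky-kz plane only
        pat = mask.pe_mask
        if pat.shape != spatial_shape:
            raise ShapeError(f"mask {pat.shape} vs k-space {spatial_shape}")
    return pat.astype(bool)


def dc_step(state: CascadeState, dc_weight: float | None = None) -> CascadeState:
    """Data consistency.  Hard mode (``dc_weight is None``): acquired samples
    are replaced by the reference exactly; the unacquired partial-Fourier
    band and unsampled points pass through unchanged.  Soft mode: gradient
    step ``k - eta * M * (k - ref)``."""
    pat = state.sampled_pattern()[None]
    k = state.current_kspace
    ref = state.reference_kspace
    if dc_weight is None:
        new = np.where(pat, ref, k)
    else:
        new = k - dc_weight * np.where(pat, k - ref, 0.0)
    return CascadeState(current_kspace=new, reference_kspace=ref, mask=state.mask)


class _Cascade(nn.Module):
    def __init__(self, cfg: VarNetConfig, rng):
        self.refiner = nn.NormUnet(2, 2, cfg.chans, cfg.strides(), rng)
        self.dc_weight = nn.Param(np.array(1.0)) if cfg.dc_mode == "soft" else None


class VarNetModel(nn.Module):
    """End-to-end variational network operating on complex multi-coil
    k-space arrays of shape ``(n_coils, *spatial)``."""

    def __init__(self, cfg: VarNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.seed = seed
        self.sens_net = nn.NormUnet(2, 2, cfg.sens_chans, cfg.strides(), rng)
        self.cascades = [_Cascade(cfg, rng) for _ in range(cfg.n_cascades)]
        # debug/ablation switch: skip refinement entirely (pure DC pipeline)
        self.force_zero_refinement = False
        self._sp_axes = tuple(range(-cfg.ndim, 0))
        self.compute_dtype = np.float64

    def astype(self, dtype) -> "VarNetModel":
        """Switch compute precision (float32 roughly halves CPU time/memory;
        gradients remain exact in that precision)."""
        dtype = np.dtype(dtype)
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
        self.compute_dtype = dtype.type
        return self

    @property
    def _cdtype(self):
        return np.complex64 if np.dtype(self.compute_dtype) == np.float32 else np.complex128

    # -- sensitivity estimation ------------------------------------------

    def _acs_pattern(self, mask: SamplingMask, spatial_shape: tuple[int, ...]) -> np.ndarray:
        cy, cz = mask.calib_extent
        if cy < 1 or cz < 1:
            raise CalibrationError("sampling mask has no calibration block")
        ny, nz = mask.pe_mask.shape
        acs2d = np.zeros((ny, nz), dtype=bool)
        ylo, zlo = (ny - cy) // 2, (nz - cz) // 2
        acs2d[ylo : ylo + cy, zlo : zlo + cz] = True
        if not np.all(mask.pe_mask[acs2d]):
            raise CalibrationError("calibration block is not fully sampled")
        if len(spatial_shape) == 3:
            return mask.pf_mask.astype(bool)[:, None, None] & acs2d[None]
        return acs2d

    def estimate_sensitivities(self, masked_kspace: np.ndarray, mask: SamplingMask, train: bool = False):
        acs = self._acs_pattern(mask, masked_kspace.shape[1:])
        acs_k = np.where(acs[None], masked_kspace, 0.0).astype(self._cdtype)
        coil_imgs = ifftnc(acs_k, axes=self._sp_axes)
        x = nn.complex_to_chan(coil_imgs)  # (n_coils, 2, *sp)
        t = nn.chan_to_complex(self.sens_net.forward(x))
        sos = np.sqrt(np.sum(np.abs(t) ** 2, axis=0))
        denom = np.maximum(sos, 1e-15)
        s = t / denom[None]
        if train:
            self._sens_cache = (t, denom)
        return s

    def _sens_backward(self, g_s: np.ndarray) -> None:
        t, d = self._sens_cache
        self._sens_cache = None
        a = np.sum((np.conj(g_s) * t).real, axis=0)
        g_t = g_s / d[None] - (a / d**3)[None] * t
        self.sens_net.backward(nn.complex_to_chan(g_t))

    # -- unrolled forward / backward -------------------------------------

    def forward(
        self,
        masked_kspace: np.ndarray,
        mask: SamplingMask,
        train: bool = False,
        return_kspace: bool = False,
    ):
        """Reconstruct a magnitude volume from masked multi-coil k-space."""
        if masked_kspace.ndim - 1 != self.cfg.ndim:
            raise ShapeError(
                f"{self.cfg.dimensionality} model got k-space of spatial rank {masked_kspace.ndim - 1}"
            )
        sp_axes = self._sp_axes
        sampled = _sampled_pattern(mask, masked_kspace.shape[1:])[None]
        masked_kspace = np.ascontiguousarray(masked_kspace, dtype=self._cdtype)
        ref = masked_kspace
        s = self.estimate_sensitivities(masked_kspace, mask, train=train)

        k = masked_kspace
        caches = []
        for casc in self.cascades:
            x = ifftnc(k, axes=sp_axes)  # per-coil images
            m = np.sum(np.conj(s) * x, axis=0)
            if self.force_zero_refinement:
                r = np.zeros_like(m)
            else:
                r = nn.chan_to_complex(casc.refiner.forward(nn.complex_to_chan(m[None])))[0]
            update = fftnc(s * r[None], axes=sp_axes)
            if casc.dc_weight is None:
                k_new = np.where(sampled, ref, k - update)
            else:
                eta = float(casc.dc_weight.value)
                k_new = k - eta * np.where(sampled, k - ref, 0.0) - update
            if train:
                caches.append((k, x, r))
            k = k_new
        # terminal hard projection guarantees sampled-set pinning in any mode
        k = np.where(sampled, ref, k)
        x_fin = ifftnc(k, axes=sp_axes)
        m_fin = np.sum(np.conj(s) * x_fin, axis=0)
        out = np.abs(m_fin)
        if train:
            self._cache = (caches, s, sampled, ref, x_fin, m_fin)
        if return_kspace:
            return out, k
        return out

    def backward(self, g_mag: np.ndarray) -> None:
        """Accumulate parameter gradients given the loss gradient w.r.t. the
        output magnitude."""
        caches, s, sampled, ref, x_fin, m_fin = self._cache
        self._cache = None
        sp_axes = self._sp_axes
        g_mag = g_mag.astype(self.compute_dtype)

        mag = np.abs(m_fin)
        g_m = g_mag * np.where(mag > 0, m_fin / np.maximum(mag, 1e-30), 0.0)
        g_s = np.conj(g_m)[None] * x_fin
        g_k = fftnc(s * g_m[None], axes=sp_axes)
        g_k = np.where(sampled, 0.0, g_k)  # terminal hard projection

        for casc, (k_in, x, r) in zip(reversed(self.cascades), reversed(caches)):
            # forward: k_out = k_in - eta*M*(k_in - ref) - update (soft)
            #          k_out = where(M, ref, k_in - update)       (hard)
            if casc.dc_weight is None:
                g_post = np.where(sampled, 0.0, g_k)
                g_kin = g_post.copy()
                g_upd = -g_post
            else:
                eta = float(casc.dc_weight.value)
                casc.dc_weight.grad += -np.sum(
                    (np.conj(g_k) * np.where(sampled, k_in - ref, 0.0)).real
                )
                g_kin = g_k - eta * np.where(sampled, g_k, 0.0)
                g_upd = -g_k
            # update = fft(s * r)
            g_p = ifftnc(g_upd, axes=sp_axes)
            g_r = np.sum(np.conj(s) * g_p, axis=0)
            g_s += np.conj(r)[None] * g_p
            if self.force_zero_refinement:
                g_m = np.zeros_like(g_r)
            else:
                g_m = nn.chan_to_complex(casc.refiner.backward(nn.complex_to_chan(g_r[None])))[0]
            # m = sum_i conj(s_i) x_i ; x = ifft(k_in)
            g_s += np.conj(g_m)[None] * x
            g_kin = g_kin + fftnc(s * g_m[None], axes=sp_axes)
            g_k = g_kin
        self._sens_backward(g_s)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def param_list(self) -> list[nn.Param]:
        return list(self.params())


def build_model(cfg: VarNetConfig, seed: int = 0) -> VarNetModel:
    """Instantiate a model (deterministic given ``seed``)."""
    return VarNetModel(cfg, seed=seed)


def count_parameters(model: VarNetModel) -> int:
    """Number of trainable scalars."""
    return sum(p.size for p in model.params())


def estimate_sensitivities(
    model: VarNetModel, masked_kspace: np.ndarray, mask: SamplingMask
) -> CoilSensitivities:
    maps = model.estimate_sensitivities(masked_kspace, mask)
    if maps.ndim == 3:  # 2D model: add a singleton slice axis for the container
        maps = maps[..., None]
    return CoilSensitivities(maps=maps)


def reconstruct(model: VarNetModel, masked_kspace: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Deterministic evaluation-mode reconstruction (magnitude volume)."""
    return model.forward(masked_kspace, mask, train=False)


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(path: str | Path, model: VarNetModel, extra: dict | None = None) -> None:
    """Versioned npz checkpoint: weights + config + seed (+ free-form extra)."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.param_list())}
    meta = {
        "schema": 1,
        "config": asdict(model.cfg),
        "seed": model.seed,
        "extra": extra or {},
    }
    np.savez(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[VarNetModel, dict]:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = VarNetConfig(**meta["config"])
        model = build_model(cfg, seed=meta["seed"])
        for i, p in enumerate(model.param_list()):
            arr = data[f"p{i}"]
            if arr.shape != p.value.shape:
                raise InvalidConfigError("checkpoint/model architecture mismatch")
            p.value = arr.astype(np.float64)
            p.grad = np.zeros_like(p.value)
    return model, meta["extra"]
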