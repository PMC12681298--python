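"""Simulation of complex-valued multi-coil undersampled raw k-space from
magnitude volumes.

Pipeline: head-mask extraction -> phase synthesis (the conjugate-symmetric
k-space of the magnitude image is corrupted by Gaussian-weighted complex
noise components and the phase of the result is taken) -> coil sensitivity
synthesis (boundary-centered anisotropic Gaussians plus modulated noise,
SoS-normalized) -> optional multiplicative bias field -> multi-coil k-space
-> readout partial Fourier + variable-density Poisson-disc undersampling.

All generators are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import find_boundaries

from .errors import (
    DegenerateMaskError,
    InfeasibleMaskError,
    InvalidConfigError,
    InvalidPFError,
    NoThresholdError,
    ShapeError,
)
from .mri_ops import fft3c, ifft3c
from .phantom_io import MagnitudeVolume, _round_half_up

__all__ = [
    "PhaseSimConfig",
    "CoilSimConfig",
    "HeadMask",
    "CoilSensitivities",
    "SamplingMask",
    "SimulatedAcquisition",
    "compute_head_mask",
    "simulate_phase",
    "simulate_coil_maps",
    "apply_bias_field",
    "compose_multicoil_kspace",
    "make_pf_mask",
    "make_poisson_mask",
    "make_sampling_mask",
    "undersample",
    "simulate_acquisition",
    "save_acquisition",
    "load_acquisition",
]


# ---------------------------------------------------------------------------
# configs and domain types
# ---------------------------------------------------------------------------

@dataclass
class PhaseSimConfig:
    """Phase synthesis parameters.

    ``sigma_noise_range`` is a ratio of the maximum magnitude intensity;
    ``sigma_gauss_range`` is a ratio of each axis length.  Defaults keep the
    noise amplitude above the signal so the phase is not biased toward zero.
    """

    n_components: int = 3
    sigma_noise_range: tuple[float, float] = (0.5, 5.0)
    sigma_gauss_range: tuple[float, float] = (0.02, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 0:
            raise InvalidConfigError("n_components must be >= 0")
        for name, (lo, hi) in (
            ("sigma_noise_range", self.sigma_noise_range),
            ("sigma_gauss_range", self.sigma_gauss_range),
        ):
            if lo <= 0 or hi < lo:
                raise InvalidConfigError(f"{name} must be positive and ordered")
        if not (0 < self.sigma_gauss_range[1] <= 1.0):
            raise InvalidConfigError("sigma_gauss_range ratios must lie in (0, 1]")


@dataclass
class CoilSimConfig:
    """Coil sensitivity synthesis parameters (ratios as in PhaseSimConfig)."""

    n_coils: int = 32
    n_components: int = 2
    sigma_noise_range: tuple[float, float] = (0.01, 0.05)
    sigma_gauss_range: tuple[float, float] = (0.02, 0.3)
    sigma_xyz_ranges: tuple[tuple[float, float], ...] = (
        (0.15, 0.5),
        (0.15, 0.5),
        (0.15, 0.5),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coils < 1:
            raise InvalidConfigError("n_coils must be >= 1")
        if self.n_components < 0:
            raise InvalidConfigError("n_components must be >= 0")
        ranges = [self.sigma_noise_range, self.sigma_gauss_range, *self.sigma_xyz_ranges]
        for lo, hi in ranges:
            if lo <= 0 or hi < lo:
                raise InvalidConfigError("all sigma ranges must be positive and ordered")


@dataclass
class HeadMask:
    mask: np.ndarray
    boundary: np.ndarray  # (n, 3) voxel coordinates on the mask surface

    def __post_init__(self) -> None:
        if self.mask.any() and len(self.boundary) == 0:
            raise DegenerateMaskError("nonempty mask with empty boundary")


@dataclass
class CoilSensitivities:
    """SoS-normalized complex coil maps, shape (n_coils, nx, ny, nz)."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        if self.maps.ndim != 4:
            raise ShapeError("coil maps must be 4D (n_coils, nx, ny, nz)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def sos(self) -> np.ndarray:
        return np.sum(np.abs(self.maps) ** 2, axis=0)


@dataclass
class SamplingMask:
    """ky-kz phase-encode mask plus one-sided readout partial-Fourier mask."""

    pe_mask: np.ndarray  # (ny, nz) binary
    pf_mask: np.ndarray  # (nx,) binary
    calib_extent: tuple[int, int] = (12, 6)
    target_R: float = 1.0

    def __post_init__(self) -> None:
        self.pe_mask = np.asarray(self.pe_mask).astype(np.uint8)
        self.pf_mask = np.asarray(self.pf_mask).astype(np.uint8)
        cy, cz = self.calib_extent
        ny, nz = self.pe_mask.shape
        sl = _center_slices((ny, nz), (cy, cz))
        if not np.all(self.pe_mask[sl] == 1):
            raise InvalidConfigError("calibration block must be fully sampled")
        d = np.diff(self.pf_mask.astype(int))
        if np.any(d < 0) or (len(d) and np.sum(d == 1) > 1):
            raise InvalidConfigError("pf_mask must be zeros on one contiguous end only")

    def combined(self, n_readout: int | None = None) -> np.ndarray:
        """Broadcastable (nx, ny, nz) binary sampling pattern."""
        return self.pf_mask[:, None, None] * self.pe_mask[None, :, :]

    @property
    def sampled_fraction(self) -> float:
        return float(self.pe_mask.mean() * self.pf_mask.mean())


@dataclass
class SimulatedAcquisition:
    """Multi-coil k-space with its mask and simulation ground truths."""

    kspace: np.ndarray  # complex (n_coils, nx, ny, nz)
    mask: SamplingMask
    truth_image: np.ndarray | None = None  # complex (nx, ny, nz)
    truth_coils: CoilSensitivities | None = None
    truth_phase: np.ndarray | None = None  # radians, in (-pi, pi]
    meta: dict = field(default_factory=dict)

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.kspace.shape[1:]


def _center_slices(shape: tuple[int, ...], extent: tuple[int, ...]) -> tuple[slice, ...]:
    out = []
    for n, c in zip(shape, extent):
        lo = (n - c) // 2
        out.append(slice(lo, lo + c))
    return tuple(out)


# ---------------------------------------------------------------------------
# head mask
# ---------------------------------------------------------------------------

def compute_head_mask(volume: MagnitudeVolume) -> HeadMask:
    """Otsu threshold -> binarize -> 4x binary erosion -> 9x binary dilation
    (6-connected) -> boundary voxels of the final mask."""
    data = volume.data
    if np.ptp(data) == 0:
        raise NoThresholdError("constant volume has no Otsu threshold")
    thr = threshold_otsu(data)
    binary = data > thr
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(binary, structure=structure, iterations=4)
    if not eroded.any():
        raise DegenerateMaskError("mask empty after 4 erosion iterations")
    mask = ndimage.binary_dilation(eroded, structure=structure, iterations=9)
    boundary = find_boundaries(mask, mode="inner")
    return HeadMask(mask=mask, boundary=np.argwhere(boundary))


# ---------------------------------------------------------------------------
# phase and coil simulation
# ---------------------------------------------------------------------------

def _gaussian_kweight(shape: tuple[int, int, int], sigmas: np.ndarray) -> np.ndarray:
    """Zero-centered (DC at array center) Gaussian weight, max 1."""
    grids = np.meshgrid(*[np.arange(s) - s // 2 for s in shape], indexing="ij")
    expo = sum((g / s) ** 2 for g, s in zip(grids, sigmas))
    return np.exp(-0.5 * expo)


def _modulated_noise(
    shape: tuple[int, int, int],
    n_components: int,
    sigma_noise_range: tuple[float, float],
    sigma_gauss_range: tuple[float, float],
    amplitude_ref: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Image-domain sum of Gaussian-weighted complex white-noise components:
    ``F^-1[ sum_j W(k; sG_j) n_j(k) ]``."""
    acc = np.zeros(shape, dtype=complex)
    axes = np.asarray(shape, dtype=float)
    for _ in range(n_components):
        s_n = rng.uniform(*sigma_noise_range) * amplitude_ref
        ratio = rng.uniform(*sigma_gauss_range)
        sigmas = ratio * axes
        w = _gaussian_kweight(shape, sigmas)
        n = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * (s_n / math.sqrt(2))
        acc += w * n
    return ifft3c(acc)


def simulate_phase(volume: MagnitudeVolume, cfg: PhaseSimConfig) -> np.ndarray:
    """Synthesize a phase volume: ``phi = arg(|x| + F^-1[sum_j W_j n_j])``.

    Equivalently, the conjugate-symmetric k-space of the magnitude image is
    corrupted by modulated noise and the phase of the result is extracted.
    Deterministic given ``cfg.seed``; output in (-pi, pi].
    """
    rng = np.random.default_rng(cfg.seed)
    mx = float(volume.data.max())
    noise = _modulated_noise(
        volume.shape, cfg.n_components, cfg.sigma_noise_range, cfg.sigma_gauss_range, mx, rng
    )
    phi = np.angle(volume.data + noise)
    # np.angle returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] contract
    phi[phi == -np.pi] = np.pi
    return phi


def _rotate_z(offsets: tuple[np.ndarray, np.ndarray, np.ndarray], theta: float):
    c, s = math.cos(theta), math.sin(theta)
    qx = c * offsets[0] + s * offsets[1]
    qy = -s * offsets[0] + c * offsets[1]
    return qx, qy, offsets[2]


def simulate_coil_maps(
    volume: MagnitudeVolume, head: HeadMask, cfg: CoilSimConfig
) -> CoilSensitivities:
    """Synthesize SoS-normalized coil sensitivities.

    Each coil is an anisotropic 3D Gaussian centered at a uniformly drawn
    head-boundary voxel, randomly rotated about the z-axis, plus independent
    Gaussian-weighted complex noise components; the stack is normalized so
    that ``sum_i |S_i|^2 == 1`` everywhere.
    """
    if len(head.boundary) == 0:
        raise DegenerateMaskError("head boundary is empty")
    rng = np.random.default_rng(cfg.seed)
    shape = volume.shape
    axes = np.asarray(shape, dtype=float)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    raw = np.empty((cfg.n_coils,) + shape, dtype=complex)
    for i in range(cfg.n_coils):
        c = head.boundary[rng.integers(len(head.boundary))]
        sigmas = np.array([rng.uniform(*r) for r in cfg.sigma_xyz_ranges]) * axes
        theta = rng.uniform(0.0, np.pi)
        qx, qy, qz = _rotate_z((grids[0] - c[0], grids[1] - c[1], grids[2] - c[2]), theta)
        g = np.exp(-0.5 * ((qx / sigmas[0]) ** 2 + (qy / sigmas[1]) ** 2 + (qz / sigmas[2]) ** 2))
        noise = _modulated_noise(
            shape, cfg.n_components, cfg.sigma_noise_range, cfg.sigma_gauss_range, 1.0, rng
        )
        raw[i] = g + noise
    sos = np.sqrt(np.sum(np.abs(raw) ** 2, axis=0))
    sos = np.where(sos == 0, 1.0, sos)
    return CoilSensitivities(maps=raw / sos[None])


def apply_bias_field(
    volume: MagnitudeVolume, coefficient: float = 0.3, order: int = 3, seed: int = 0
) -> MagnitudeVolume:
    """Multiply the volume by ``exp(P(r))`` with P a random polynomial of
    total degree <= ``order`` over [-1, 1]-normalized coordinates and
    coefficients uniform in [-coefficient, +coefficient]."""
    if coefficient < 0 or order < 0:
        raise InvalidConfigError("coefficient and order must be >= 0")
    rng = np.random.default_rng(seed)
    shape = volume.shape
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    poly = np.zeros(shape)
    for a in range(order + 1):
        for b in range(order + 1 - a):
            for c in range(order + 1 - a - b):
                coef = rng.uniform(-coefficient, coefficient)
                poly += coef * gx**a * gy**b * gz**c
    field_ = np.exp(poly)
    return MagnitudeVolume(
        data=volume.data * field_,
        spacing=volume.spacing,
        meta={**volume.meta, "bias_field": {"coefficient": coefficient, "order": order, "seed": seed}},
    )


# ---------------------------------------------------------------------------
# k-space composition and sampling masks
# ---------------------------------------------------------------------------

def compose_multicoil_kspace(
    volume: MagnitudeVolume, phase: np.ndarray, coils: CoilSensitivities
) -> SimulatedAcquisition:
    """Fully sampled multi-coil k-space of ``|x| exp(i phi)`` under the
    centered unitary 3D transform."""
    if phase.shape != volume.shape or coils.maps.shape[1:] != volume.shape:
        raise ShapeError(
            f"shape mismatch: volume {volume.shape}, phase {phase.shape}, coils {coils.maps.shape}"
        )
    truth = volume.data * np.exp(1j * phase)
    kspace = fft3c(coils.maps * truth[None])
    nx, ny, nz = volume.shape
    mask = SamplingMask(
        pe_mask=np.ones((ny, nz), dtype=np.uint8),
        pf_mask=np.ones(nx, dtype=np.uint8),
        calib_extent=(min(12, ny), min(6, nz)),
        target_R=1.0,
    )
    return SimulatedAcquisition(
        kspace=kspace, mask=mask, truth_image=truth, truth_coils=coils, truth_phase=phase
    )


def make_pf_mask(n_readout: int, pf_fraction: float) -> np.ndarray:
    """One-sided readout partial-Fourier mask: ``round(pf_fraction*n)``
    contiguous zeros at the low-index end (the omitted asymmetric band),
    ones elsewhere.  Rounding is half-up."""
    if not (0.0 <= pf_fraction < 0.5):
        raise InvalidPFError(f"pf_fraction must be in [0, 0.5), got {pf_fraction}")
    n_zero = _round_half_up(pf_fraction * n_readout)
    mask = np.ones(n_readout, dtype=np.uint8)
    mask[:n_zero] = 0
    return mask


_VD_ALPHA = 2.0  # radius growth toward the k-space edge


def _poisson_draw(
    ny: int, nz: int, r0: float, calib: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Variable-density Poisson-disc dart throwing on an (ny, nz) grid.

    Local radius r(p) = r0 * (1 + alpha * ||p - center|| / rmax); a candidate
    is rejected if an accepted point q lies closer than min(r(p), r(q)).
    """
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    iy, iz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    dist = np.hypot(iy - cy, iz - cz)
    rmax = float(dist.max()) or 1.0
    radius = r0 * (1.0 + _VD_ALPHA * dist / rmax)

    order = rng.permutation(ny * nz)
    accepted = np.zeros((ny, nz), dtype=bool)
    for flat in order:
        py, pz = divmod(int(flat), nz)
        rp = radius[py, pz]
        w = int(math.ceil(rp))
        ylo, yhi = max(0, py - w), min(ny, py + w + 1)
        zlo, zhi = max(0, pz - w), min(nz, pz + w + 1)
        sub = accepted[ylo:yhi, zlo:zhi]
        if sub.any():
            qy, qz = np.nonzero(sub)
            qy = qy + ylo
            qz = qz + zlo
            d = np.hypot(qy - py, qz - pz)
            rq = radius[qy, qz]
            if np.any(d < np.minimum(rp, rq)):
                continue
        accepted[py, pz] = True
    accepted[_center_slices((ny, nz), calib)] = True
    return accepted


@lru_cache(maxsize=128)
def _calibrate_r0(ny: int, nz: int, R: float, calib: tuple[int, int]) -> float:
    """Bisection on r0 so the sampled fraction (calibration included) hits
    1/R.  Uses a fixed internal seed; the final user draw reuses r0."""
    target = 1.0 / R
    rng_seed = 1234
    lo, hi = 0.5, float(max(ny, nz))
    # fraction is monotone decreasing in r0
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        frac = _poisson_draw(ny, nz, mid, calib, np.random.default_rng(rng_seed)).mean()
        if frac > target:
            lo = mid
        else:
            hi = mid
        if abs(frac - target) / target < 0.02:
            return mid
    return 0.5 * (lo + hi)


def make_poisson_mask(
    ny: int, nz: int, R: float, calib: tuple[int, int] = (12, 6), seed: int = 0
) -> np.ndarray:
    """Variable-density Poisson-disc ky-kz mask with a fully sampled centered
    calibration block; achieved fraction within 10% relative of 1/R."""
    if R < 1:
        raise InvalidConfigError(f"acceleration R must be >= 1, got {R}")
    cy, cz = calib
    if cy > ny or cz > nz:
        raise InvalidConfigError(f"calibration {calib} does not fit in ({ny}, {nz})")
    if R == 1:
        return np.ones((ny, nz), dtype=np.uint8)
    min_frac = (cy * cz) / (ny * nz)
    if 1.0 / R < min_frac:
        raise InfeasibleMaskError(
            f"target fraction 1/R={1.0 / R:.4f} below calibration floor {min_frac:.4f}"
        )
    r0 = _calibrate_r0(ny, nz, float(R), (int(cy), int(cz)))
    mask = _poisson_draw(ny, nz, r0, (int(cy), int(cz)), np.random.default_rng(seed))
    return mask.astype(np.uint8)


def make_sampling_mask(
    shape: tuple[int, int, int],
    R: float,
    pf_fraction: float = 0.0,
    calib: tuple[int, int] = (12, 6),
    seed: int = 0,
) -> SamplingMask:
    nx, ny, nz = shape
    return SamplingMask(
        pe_mask=make_poisson_mask(ny, nz, R, calib=calib, seed=seed),
        pf_mask=make_pf_mask(nx, pf_fraction),
        calib_extent=calib,
        target_R=float(R),
    )


def undersample(acq: SimulatedAcquisition, mask: SamplingMask) -> SimulatedAcquisition:
    """Zero k-space outside the sampling pattern; sampled entries unchanged."""
    nx, ny, nz = acq.shape
    if mask.pe_mask.shape != (ny, nz) or mask.pf_mask.shape != (nx,):
        raise ShapeError(
            f"mask dims {mask.pe_mask.shape}/{mask.pf_mask.shape} vs kspace {acq.kspace.shape}"
        )
    pattern = mask.combined()[None]
    return SimulatedAcquisition(
        kspace=np.where(pattern.astype(bool), acq.kspace, 0.0),
        mask=mask,
        truth_image=acq.truth_image,
        truth_coils=acq.truth_coils,
        truth_phase=acq.truth_phase,
        meta=dict(acq.meta),
    )


# ---------------------------------------------------------------------------
# end-to-end convenience and HDF5 container
# ---------------------------------------------------------------------------

def simulate_acquisition(
    volume: MagnitudeVolume,
    R: float = 1.0,
    pf_fraction: float = 0.0,
    calib: tuple[int, int] = (12, 6),
    seed: int = 0,
    phase_cfg: PhaseSimConfig | None = None,
    coil_cfg: CoilSimConfig | None = None,
    bias_coefficient: float = 0.3,
    bias_order: int = 3,
) -> SimulatedAcquisition:
    """Full simulation pipeline for one magnitude volume.

    Derives independent per-stage seeds from ``seed``; the Poisson mask uses
    its own sub-seed so it can be re-randomized independently downstream.
    """
    ss = np.random.SeedSequence(seed)
    s_phase, s_coil, s_bias, s_mask = [int(s.generate_state(1)[0]) for s in ss.spawn(4)]
    phase_cfg = phase_cfg or PhaseSimConfig(seed=s_phase)
    coil_cfg = coil_cfg or CoilSimConfig(seed=s_coil)
    if bias_coefficient > 0:
        volume = apply_bias_field(volume, bias_coefficient, bias_order, seed=s_bias)
    head = compute_head_mask(volume)
    phase = simulate_phase(volume, phase_cfg)
    coils = simulate_coil_maps(volume, head, coil_cfg)
    acq = compose_multicoil_kspace(volume, phase, coils)
    mask = make_sampling_mask(volume.shape, R, pf_fraction, calib=calib, seed=s_mask)
    out = undersample(acq, mask)
    out.meta.update({"seed": seed, "R": R, "pf_fraction": pf_fraction})
    return out


def save_acquisition(acq: SimulatedAcquisition, path: str | Path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("kspace", data=acq.kspace.astype(np.complex64))
        f.create_dataset("pe_mask", data=acq.mask.pe_mask.astype(np.uint8))
        f.create_dataset("pf_mask", data=acq.mask.pf_mask.astype(np.uint8))
        if acq.truth_coils is not None:
            f.create_dataset("sens", data=acq.truth_coils.maps.astype(np.complex64))
        if acq.truth_image is not None:
            f.create_dataset("truth", data=acq.truth_image.astype(np.complex64))
        if acq.truth_phase is not None:
            f.create_dataset("truth_phase", data=acq.truth_phase.astype(np.float32))
        f.attrs["target_R"] = acq.mask.target_R
        f.attrs["calib_extent"] = list(acq.mask.calib_extent)
        f.attrs["seed"] = int(acq.meta.get("seed", -1))
        f.attrs["provenance"] = str(acq.meta)


def load_acquisition(path: str | Path) -> SimulatedAcquisition:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(str(path), "r") as f:
        kspace = f["kspace"][...].astype(complex)
        mask = SamplingMask(
            pe_mask=f["pe_mask"][...],
            pf_mask=f["pf_mask"][...],
            calib_extent=tuple(int(v) for v in f.attrs["calib_extent"]),
            target_R=float(f.attrs["target_R"]),
        )
        truth = f["truth"][...].astype(complex) if "truth" in f else None
        sens = CoilSensitivities(f["sens"][...].astype(complex)) if "sens" in f else None
        phase = f["truth_phase"][...].astype(float) if "truth_phase" in f else None
        meta = {"seed": int(f.attrs.get("seed", -1))}
    return SimulatedAcquisition(
        kspace=kspace, mask=mask, truth_image=truth, truth_coils=sens, truth_phase=phase, meta=meta
    )
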