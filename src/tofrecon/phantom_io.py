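"""Volume I/O, slab splitting and the synthetic TOF-like angiography phantom.

The phantom stands in for real magnitude angiograms: an ellipsoidal head of
moderate-intensity tissue with smooth low-frequency texture, threaded by
bright, thin, connected tubular vessels.  Everything downstream (k-space
simulation, reconstruction, metrics, training) is testable on it offline.

Array convention: in-plane axes first, slice axis LAST, i.e. shape
``(nx, ny, nz)`` with ``nz`` the (thin) slab direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .errors import DimensionalityError, InfeasibleSplitError, InvalidConfigError

__all__ = [
    "MagnitudeVolume",
    "SlabStack",
    "PhantomConfig",
    "generate_tof_phantom",
    "split_slabs",
    "concat_slabs",
    "read_volume",
    "write_volume",
]


def _round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


@dataclass
class MagnitudeVolume:
    """A real, nonnegative 3D magnitude volume with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"MagnitudeVolume requires a 3D array, got ndim={self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise InvalidConfigError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise InvalidConfigError("volume contains negative values")
        nx, ny, nz = self.data.shape
        if not (nx >= nz and ny >= nz):
            raise InvalidConfigError(
                f"slab-thin convention violated: in-plane {nx}x{ny} must be >= slice count {nz}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SlabStack:
    """Ordered overlapping slabs covering a source volume along the slice axis."""

    slabs: list[MagnitudeVolume]
    overlap_slices: int
    source_extent: int

    def __post_init__(self) -> None:
        if not self.slabs:
            raise InvalidConfigError("SlabStack needs at least one slab")
        shapes = {s.shape for s in self.slabs}
        if len(shapes) != 1:
            raise InvalidConfigError("slabs must share a common shape")
        n = len(self.slabs)
        L = self.slabs[0].shape[2]
        if n * L - (n - 1) * self.overlap_slices != self.source_extent:
            raise InvalidConfigError("slab arithmetic does not cover the source extent")


@dataclass
class PhantomConfig:
    """Parameters of the synthetic TOF-like phantom."""

    shape: tuple[int, int, int] = (64, 64, 24)
    n_vessels: int = 6
    vessel_radius_range: tuple[float, float] = (1.0, 2.0)
    vessel_intensity: float = 1.0
    tissue_intensity: float = 0.35
    head_axes: tuple[float, float, float] | None = None
    texture_scale: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 16 for s in self.shape):
            raise InvalidConfigError(f"phantom shape {self.shape}: each axis must be >= 16")
        if not (self.vessel_intensity > self.tissue_intensity > 0):
            raise InvalidConfigError("need vessel_intensity > tissue_intensity > 0")
        lo, hi = self.vessel_radius_range
        if lo < 1.0 or hi < lo:
            raise InvalidConfigError("vessel radii must be >= 1 voxel and ordered")
        if self.head_axes is None:
            self.head_axes = tuple(0.45 * s for s in self.shape)
        if 2.0 * hi >= min(self.shape):
            raise InvalidConfigError("shape too small for requested vessel radius")


def _head_ellipsoid(shape: tuple[int, int, int], axes: tuple[float, float, float]) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) - (s - 1) / 2.0 for s in shape], indexing="ij")
    q = sum((g / a) ** 2 for g, a in zip(grids, axes))
    return q <= 1.0


def generate_tof_phantom(config: PhantomConfig) -> MagnitudeVolume:
    """Generate a deterministic TOF-like phantom from ``config``.

    Tissue fills an ellipsoidal head with smooth low-frequency texture;
    vessels are smooth tubes (cubic-spline centerlines with Gaussian
    cross-sections) rendered at ``vessel_intensity``; outside the head the
    volume is exactly zero.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.shape
    head = _head_ellipsoid(shape, config.head_axes)

    # low-frequency multiplicative texture on the tissue
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=[max(2.0, s / 10.0) for s in shape])
    smooth = smooth / (np.abs(smooth).max() + 1e-12)
    tissue = config.tissue_intensity * (1.0 + config.texture_scale / config.tissue_intensity * smooth)
    tissue = np.clip(tissue, 0.05 * config.tissue_intensity, None)

    vol = np.where(head, tissue, 0.0)

    # vessels: spline centerlines through the head, Gaussian tube profiles
    axes = np.asarray(config.head_axes)
    center = (np.asarray(shape) - 1) / 2.0
    for _ in range(config.n_vessels):
        radius = rng.uniform(*config.vessel_radius_range)
        n_ctrl = 5
        # control points inside a slightly shrunk head ellipsoid, ordered
        # along a random dominant direction so the tube traverses the head
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        ts = np.linspace(-0.85, 0.85, n_ctrl)
        ctrl = center + np.outer(ts, direction * axes)
        jitter = rng.standard_normal((n_ctrl, 3)) * (0.15 * axes)
        jitter[0] *= 0.3  # keep endpoints near the head surface
        jitter[-1] *= 0.3
        ctrl = ctrl + jitter
        spline = CubicSpline(np.linspace(0.0, 1.0, n_ctrl), ctrl, axis=0)
        # arc-length-ish dense sampling
        t = np.linspace(0.0, 1.0, 8 * max(shape))
        pts = spline(t)
        inside = np.all((pts >= 0) & (pts <= np.asarray(shape) - 1), axis=1)
        pts = pts[inside]
        if len(pts) == 0:
            continue
        mark = np.zeros(shape, dtype=bool)
        idx = np.round(pts).astype(int)
        mark[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        dist = ndimage.distance_transform_edt(~mark)
        profile = config.vessel_intensity * np.exp(-(dist**2) / (2.0 * radius**2))
        vol = np.maximum(vol, np.where(head, profile, 0.0))

    vol = np.where(head, vol, 0.0)
    return MagnitudeVolume(
        data=vol.astype(np.float64),
        spacing=(1.0, 1.0, 1.0),
        meta={"source": "tof_phantom", "seed": config.seed},
    )


def _feasible_lengths(source: int, n_slabs: int, overlap_fraction: float) -> list[int]:
    out = []
    for L in range(1, source + 1):
        v = _round_half_up(overlap_fraction * L)
        if v >= L:
            continue
        if n_slabs * L - (n_slabs - 1) * v == source:
            out.append(L)
    return out


def split_slabs(volume: MagnitudeVolume, n_slabs: int, overlap_fraction: float) -> SlabStack:
    """Split along the slice axis into ``n_slabs`` uniformly overlapping slabs.

    The slab length ``L`` and integer overlap ``v = round(overlap_fraction*L)``
    (ties round half-up) must satisfy ``n*L - (n-1)*v == nz`` exactly; the
    smallest feasible ``L`` is used.
    """
    if n_slabs < 1:
        raise InvalidConfigError("n_slabs must be >= 1")
    if not (0.0 <= overlap_fraction < 1.0):
        raise InvalidConfigError("overlap_fraction must be in [0, 1)")
    source = volume.shape[2]
    if n_slabs == 1:
        return SlabStack(slabs=[volume], overlap_slices=0, source_extent=source)
    sols = _feasible_lengths(source, n_slabs, overlap_fraction)
    if not sols:
        # report achievable neighbouring slice counts for diagnostics
        achievable = sorted(
            {
                n_slabs * L - (n_slabs - 1) * _round_half_up(overlap_fraction * L)
                for L in range(1, source + 2)
                if _round_half_up(overlap_fraction * L) < L
            }
        )
        below = max((s for s in achievable if s < source), default=None)
        above = min((s for s in achievable if s > source), default=None)
        raise InfeasibleSplitError(
            f"no integer slab length tiles {source} slices with n_slabs={n_slabs}, "
            f"overlap_fraction={overlap_fraction}; nearest feasible slice counts: "
            f"{below} (below), {above} (above)"
        )
    L = sols[0]
    v = _round_half_up(overlap_fraction * L)
    step = L - v
    slabs = []
    for i in range(n_slabs):
        lo = i * step
        sub = volume.data[:, :, lo : lo + L]
        slabs.append(
            MagnitudeVolume(
                data=sub.copy(),
                spacing=volume.spacing,
                meta={**volume.meta, "slab_index": i, "slab_start": lo},
            )
        )
    return SlabStack(slabs=slabs, overlap_slices=v, source_extent=source)


def concat_slabs(stack: SlabStack) -> MagnitudeVolume:
    """Recombine a SlabStack by overlap-trimmed concatenation (exact inverse
    of :func:`split_slabs` for untouched slabs)."""
    v = stack.overlap_slices
    parts = [stack.slabs[0].data]
    for slab in stack.slabs[1:]:
        parts.append(slab.data[:, :, v:])
    data = np.concatenate(parts, axis=2)
    assert data.shape[2] == stack.source_extent
    return MagnitudeVolume(data=data, spacing=stack.slabs[0].spacing, meta=dict(stack.slabs[0].meta))


def write_volume(volume: MagnitudeVolume, path: str | Path) -> None:
    """Write a volume as float32 NIfTI; spacing goes into the affine/zooms."""
    volume.validate()
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> MagnitudeVolume:
    """Read a 3D single-channel NIfTI volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"expected a 3D volume, got ndim={data.ndim}")
    # NIfTI stores zooms as float32; round to micrometre precision so that
    # exact mm spacings survive the roundtrip
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    return MagnitudeVolume(
        data=np.ascontiguousarray(data, dtype=np.float32).astype(np.float64),
        spacing=spacing,
        meta={"source_path": str(path)},
    )
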