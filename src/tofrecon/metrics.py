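"""Evaluation metrics: PSNR, 3D SSIM, NMSE, axial MIP, vessel masks and
vessel-masked SSIM (VM-SSIM).

Conventions pinned here (and in the tests): PSNR peak is the maximum of the
reference volume; SSIM uses a uniform 7x7(x7) window with K1=0.01, K2=0.03
and dynamic range equal to the reference maximum; metrics are computed over
the whole 3D volume, VM-SSIM over axial-MIP vessel pixels only.  The vessel
mask is always derived from the reference, never from the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.filters import frangi
from skimage.metrics import structural_similarity
from skimage.morphology import remove_small_objects

from .errors import EmptyMaskError, ShapeError, UndefinedMetricError, WindowError

__all__ = [
    "MetricsRecord",
    "VesselMask",
    "psnr",
    "nmse",
    "ssim3d",
    "mip_axial",
    "vessel_mask",
    "vm_ssim",
    "evaluate_all",
]

PSNR_INF = float("inf")
SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_WIN = 7
VESSEL_SCALES = (1.0, 2.0, 3.0)
VESSEL_THRESHOLD = 0.01  # on Frangi vesselness of the max-normalized MIP
VESSEL_MIN_OBJECT = 10
VESSEL_BRIGHTNESS = 1.5  # vessels must exceed this multiple of the head median
VESSEL_HEAD_FRACTION = 0.05
VESSEL_HEAD_EROSION = 2


@dataclass
class MetricsRecord:
    psnr: float
    ssim: float
    nmse: float
    vm_ssim: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class VesselMask:
    mask: np.ndarray  # binary, over the axial MIP grid
    source: str = ""


def _check_pair(recon: np.ndarray, reference: np.ndarray) -> None:
    if recon.shape != reference.shape:
        raise ShapeError(f"shape mismatch {recon.shape} vs {reference.shape}")


def nmse(recon: np.ndarray, reference: np.ndarray) -> float:
    """``||recon - ref||^2 / ||ref||^2`` over the whole volume."""
    _check_pair(recon, reference)
    denom = float(np.sum(np.abs(reference) ** 2))
    if denom == 0:
        raise UndefinedMetricError("NMSE undefined for an all-zero reference")
    return float(np.sum(np.abs(recon - reference) ** 2) / denom)


def psnr(recon: np.ndarray, reference: np.ndarray) -> float:
    """``10 log10(peak^2 / MSE)`` with peak = max(reference); +inf for an
    exact match."""
    _check_pair(recon, reference)
    peak = float(np.max(reference))
    if peak <= 0:
        raise UndefinedMetricError("PSNR undefined for a nonpositive reference peak")
    mse = float(np.mean(np.abs(recon - reference) ** 2))
    if mse == 0:
        return PSNR_INF
    return float(10.0 * np.log10(peak**2 / mse))


def _ssim(recon: np.ndarray, reference: np.ndarray, full: bool = False):
    if min(recon.shape) < SSIM_WIN:
        raise WindowError(f"SSIM window {SSIM_WIN} larger than extent {recon.shape}")
    peak = float(np.max(reference))
    if peak <= 0:
        raise UndefinedMetricError("SSIM undefined for a nonpositive reference peak")
    return structural_similarity(
        reference.astype(np.float64),
        recon.astype(np.float64),
        win_size=SSIM_WIN,
        gaussian_weights=False,
        data_range=peak,
        K1=SSIM_K1,
        K2=SSIM_K2,
        full=full,
    )


def ssim3d(recon: np.ndarray, reference: np.ndarray) -> float:
    """Mean local SSIM with a uniform 7x7x7 window."""
    _check_pair(recon, reference)
    return float(_ssim(recon, reference))


def mip_axial(volume: np.ndarray) -> np.ndarray:
    """Maximum intensity projection along the slice (last) axis."""
    return np.max(volume, axis=-1)


def vessel_mask(reference_mip: np.ndarray, source: str = "") -> VesselMask:
    """Binary vessel mask from a reference MIP.

    Recipe (reference-only, scale-invariant, phantom-validated): multiscale
    Frangi vesselness at scales {1,2,3} px on the max-normalized MIP,
    thresholded at 0.01, restricted to the (slightly eroded) head region and
    to bright pixels (> 1.5x the head median, the inflow-enhancement cue of
    TOF angiograms), then small objects (< 10 px) removed.
    """
    if np.ptp(reference_mip) == 0:
        raise EmptyMaskError("constant MIP yields no vessel mask")
    mip = reference_mip.astype(np.float64)
    mipn = mip / mip.max()
    vness = frangi(mipn, sigmas=VESSEL_SCALES, black_ridges=False)
    head = mipn > VESSEL_HEAD_FRACTION
    if not head.any():
        raise EmptyMaskError("empty head region in MIP")
    interior = ndimage.binary_erosion(head, iterations=VESSEL_HEAD_EROSION)
    bright = mip > VESSEL_BRIGHTNESS * float(np.median(mip[head]))
    raw = (vness > VESSEL_THRESHOLD) & interior & bright
    mask = remove_small_objects(raw, min_size=VESSEL_MIN_OBJECT)
    if not mask.any():
        raise EmptyMaskError("vessel mask empty after small-object removal")
    return VesselMask(mask=mask, source=source)


def vm_ssim(
    recon: np.ndarray, reference: np.ndarray, mask: VesselMask | None = None
) -> float:
    """SSIM map between axial MIPs averaged over vessel-mask pixels only.

    The mask defaults to :func:`vessel_mask` of the reference MIP.
    """
    _check_pair(recon, reference)
    mip_r = mip_axial(recon)
    mip_ref = mip_axial(reference)
    if mask is None:
        mask = vessel_mask(mip_ref)
    if not mask.mask.any():
        raise UndefinedMetricError("empty vessel mask")
    _, ssim_map = _ssim(mip_r, mip_ref, full=True)
    return float(np.mean(ssim_map[mask.mask]))


def evaluate_all(recon: np.ndarray, reference: np.ndarray) -> MetricsRecord:
    """The full record used throughout evaluation."""
    return MetricsRecord(
        psnr=psnr(recon, reference),
        ssim=ssim3d(recon, reference),
        nmse=nmse(recon, reference),
        vm_ssim=vm_ssim(recon, reference),
    )
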