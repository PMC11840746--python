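"""Frequency-domain vascular regional segmentation (HVD / LVD / AV).

The normalized HbT volume I(x,y,z) is transformed with a 3D FFT, the
zero-frequency component is shifted to the center, and a Gaussian
high-pass filter

    H(u,v,w) = 1 - exp(-D^2 / (2 D0^2))

is applied elementwise, where D is the centered frequency radius measured
in physical units (cycles/mm, so anisotropic voxels are handled
isotropically in physical space) and D0 is the cutoff radius. The filtered
volume I' is used exclusively to segment regions of high vascular density:
positive tumor values of I' are binarized with an Otsu threshold computed
on log-intensities (the filtered HbT intensities are approximately
log-normal), giving the HVD mask; the low-vascular-density mask is the
remainder of the tumor minus the avascular voxels.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    LABEL_AV,
    LABEL_BACKGROUND,
    LABEL_HVD,
    LABEL_LVD,
    HbTVolume,
    RegionLabelVolume,
    VoxelGrid,
)

__all__ = [
    "normalize_unit",
    "nyquist_cutoff_radius",
    "gaussian_highpass_3d",
    "otsu_lognormal_threshold",
    "segment_regions",
]

logger = logging.getLogger(__name__)

OTSU_BINS = 256


def normalize_unit(hbt: HbTVolume | np.ndarray) -> np.ndarray:
    """Min-max normalize a volume to [0, 1] over the full volume."""
    vol = hbt.values if isinstance(hbt, HbTVolume) else np.asarray(hbt, dtype=float)
    lo, hi = float(vol.min()), float(vol.max())
    if hi <= lo:
        raise ValueError("constant volume: unit normalization (and segmentation) undefined")
    return (vol - lo) / (hi - lo)


def nyquist_cutoff_radius(grid: VoxelGrid, cutoff_fraction: float) -> float:
    """D0 in cycles/mm: ``cutoff_fraction`` of the smallest axis Nyquist."""
    if not (0 < cutoff_fraction <= 1):
        raise ValueError("cutoff_fraction must be in (0, 1]")
    nyquist = min(1.0 / (2.0 * s) for s in grid.spacing)
    return cutoff_fraction * nyquist


def _frequency_radius(shape: tuple[int, int, int], spacing: tuple[float, float, float]) -> np.ndarray:
    """Centered frequency radius (cycles/mm) on the fftshifted grid."""
    freqs = [
        np.fft.fftshift(np.fft.fftfreq(n, d=s)) for n, s in zip(shape, spacing)
    ]
    fe, fa, fl = np.meshgrid(*freqs, indexing="ij")
    return np.sqrt(fe**2 + fa**2 + fl**2)


def gaussian_highpass_3d(
    vol: np.ndarray,
    grid: VoxelGrid,
    cutoff_fraction: float = 0.02,
) -> np.ndarray:
    """Apply the Gaussian high-pass filter in the 3D Fourier domain.

    Returns the real filtered volume I'. The DC component is removed
    exactly (H(0) = 0), so mean(I') ~ 0; the imaginary residue of the
    inverse transform is asserted to be negligible and discarded.
    """
    vol = np.asarray(vol, dtype=float)
    grid.check_compatible(vol, "volume")
    if min(vol.shape) < 4:
        raise ValueError(f"volume shape {vol.shape} too small to filter (need >= 4 per axis)")
    if not np.isfinite(vol).all():
        raise ValueError("volume contains non-finite values")

    d0 = nyquist_cutoff_radius(grid, cutoff_fraction)
    D = _frequency_radius(vol.shape, grid.spacing)
    H = 1.0 - np.exp(-(D**2) / (2.0 * d0**2))

    F = np.fft.fftshift(np.fft.fftn(vol))
    out = np.fft.ifftn(np.fft.ifftshift(F * H))
    scale = max(np.abs(out.real).max(), 1e-300)
    imag_residue = np.abs(out.imag).max() / scale
    if imag_residue > 1e-8:
        raise AssertionError(
            f"imaginary residue {imag_residue:g} after inverse FFT exceeds 1e-8"
        )
    filtered = out.real
    if abs(filtered.mean()) > 1e-8 * scale:
        raise AssertionError("DC component not removed by the high-pass filter")
    return filtered


def otsu_lognormal_threshold(values: np.ndarray) -> float:
    """Otsu threshold for log-normally distributed positive intensities.

    The between-class variance is maximized over the 255 cut points of a
    256-bin histogram of log-intensities; the threshold is returned on the
    original intensity scale (values >= threshold form the foreground).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0 or (values <= 0).any():
        raise ValueError("all values must be strictly positive")
    if np.unique(values).size < 2:
        raise ValueError("need at least two distinct values")

    logv = np.log(values)
    counts, edges = np.histogram(logv, bins=OTSU_BINS)
    counts = counts.astype(float)

    # Between-class variance at every cut k (class 0: bins <= k).
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    mu_cum = np.cumsum(p * centers)
    mu_total = mu_cum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu_cum[:-1] / w0
        mu1 = (mu_total - mu_cum[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    k = int(np.argmax(sigma_b))
    return float(np.exp(edges[k + 1]))


def segment_regions(
    filtered: np.ndarray,
    tumor: np.ndarray,
    av: np.ndarray,
    grid: VoxelGrid,
) -> tuple[RegionLabelVolume, float]:
    """Partition the tumor into HVD / LVD / AV from the filtered volume.

    HVD voxels are tumor voxels whose (positive) filtered intensity meets
    the log-normal Otsu threshold; AV voxels come from the noise
    thresholding step; LVD is the remainder, so the three labels tile the
    tumor exactly. Returns the label volume and the threshold used.
    """
    tumor = np.asarray(tumor, dtype=bool)
    av = np.asarray(av, dtype=bool)
    grid.check_compatible(filtered, "filtered volume")
    grid.check_compatible(tumor, "tumor mask")
    grid.check_compatible(av, "AV mask")
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    if (av & ~tumor).any():
        raise ValueError("AV mask extends outside the tumor mask")

    pos = tumor & (filtered > 0)
    if pos.sum() < 2 or np.unique(filtered[pos]).size < 2:
        logger.warning("no usable positive filtered values in tumor: HVD empty")
        threshold = np.inf
        hvd = np.zeros_like(tumor)
    else:
        threshold = otsu_lognormal_threshold(filtered[pos])
        hvd = pos & (filtered >= threshold)

    labels = np.full(tumor.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[tumor] = LABEL_LVD
    labels[av & ~hvd] = LABEL_AV
    labels[hvd] = LABEL_HVD

    result = RegionLabelVolume(grid=grid, labels=labels)
    result.assert_partition(tumor)  # the partition identity, on every run
    if not (result.hvd.any() or result.lvd.any()):
        logger.warning("entire tumor is avascular: HVD and LVD are empty")
    return result, threshold
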