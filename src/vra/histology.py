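"""Immunofluorescence processing and histology-imaging validation.

Covers channel binarization, DAPI-based tumor masking, demons mask
registration (coarse center-of-mass alignment followed by a
coarse-to-fine diffeomorphic-demons refinement), the 1 mm grid
CD31-versus-HVD correlation, and the pixel-count positivity ratios
(Ki-67 index, vascular normalization index aSMA+/CD31+, perfusion ratio
TL+/CD31+).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .regional import pearson_correlation
from .types import LABEL_BACKGROUND, LABEL_HVD, RegionLabelVolume

__all__ = [
    "binarize_channel",
    "tumor_mask_from_dapi",
    "register_demons",
    "warp_image",
    "dice",
    "grid_correlation",
    "GridCorrelationResult",
    "positivity_ratio",
    "downsample_mean",
]

logger = logging.getLogger(__name__)


def binarize_channel(channel: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Min-max normalize a channel, then binarize at ``threshold``.

    The threshold is on the normalized [0, 1] scale and should sit just
    above the autofluorescence background.
    """
    channel = np.asarray(channel, dtype=float)
    hi = channel.max()
    if hi <= 0:
        raise ValueError("channel is all zero: nothing to binarize")
    norm = (channel - channel.min()) / (hi - channel.min()) if hi > channel.min() else channel / hi
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be within the normalized [0, 1] range")
    if threshold == 0:
        return channel > 0
    return norm >= threshold


def tumor_mask_from_dapi(
    dapi: np.ndarray, threshold: float = 0.1, min_component_px: int = 64
) -> np.ndarray:
    """Segment the tumor region from the DAPI nuclear stain.

    Binarize, fill holes, and keep the largest 8-connected component
    (dropping specks below ``min_component_px``).
    """
    binary = binarize_channel(dapi, threshold)
    filled = ndimage.binary_fill_holes(binary)
    labeled, n = ndimage.label(filled, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        raise ValueError("DAPI segmentation produced an empty tumor mask")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_component_px:
        raise ValueError("largest DAPI component is below min_component_px")
    return labeled == best


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


@dataclass
class DisplacementField:
    """Per-pixel displacement (mm) mapping fixed coordinates into moving space."""

    field_mm: np.ndarray  # (H, W, 2), (row, col) components
    pixel_size_mm: float

    @property
    def field_px(self) -> np.ndarray:
        return self.field_mm / self.pixel_size_mm


def _mask_to_sitk(mask: np.ndarray, smooth_px: float) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(mask, dtype=np.float32))
    if smooth_px > 0:
        img = sitk.SmoothingRecursiveGaussian(img, smooth_px)
    return img


def _center_of_mass_shift(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    cm_m = np.array(ndimage.center_of_mass(moving))
    cm_f = np.array(ndimage.center_of_mass(fixed))
    return cm_m - cm_f  # displacement from fixed frame into moving frame


def warp_image(
    image: np.ndarray, field_px: np.ndarray, order: int = 1
) -> np.ndarray:
    """Resample ``image`` through a (row, col) displacement field in pixels."""
    h, w = image.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rr + field_px[..., 0], cc + field_px[..., 1]])
    return ndimage.map_coordinates(
        np.asarray(image, dtype=float), coords, order=order, mode="constant"
    )


def register_demons(
    moving: np.ndarray,
    fixed: np.ndarray,
    pixel_size_mm: float = 1.0,
    iterations: int = 50,
    smoothing_sigma: float = 2.0,
    pyramid_levels: int = 3,
) -> DisplacementField:
    """Register a moving binary mask onto a fixed one with demons forces.

    The masks are first coarsely aligned by their centers of mass; a
    multi-resolution diffeomorphic demons refinement (Gaussian-regularized
    update field, ``smoothing_sigma`` px) then recovers residual
    deformation. The returned field maps fixed-image coordinates into the
    moving image (suitable for pulling the moving image onto the fixed
    grid). The mask Dice after warping never falls below the
    pre-registration Dice: if the refinement fails to improve on the
    coarse (or identity) alignment, the better field is returned.
    """
    moving = np.asarray(moving, dtype=bool)
    fixed = np.asarray(fixed, dtype=bool)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed masks must share one shape")
    if not moving.any() or not fixed.any():
        raise ValueError("both masks must be non-empty")

    h, w = fixed.shape
    zero = np.zeros((h, w, 2), dtype=float)
    candidates = [zero]

    shift = _center_of_mass_shift(moving, fixed)
    com_field = np.broadcast_to(shift, (h, w, 2)).astype(float)
    candidates.append(com_field)

    # Demons refinement of the center-of-mass-aligned moving mask.
    moving_aligned = warp_image(moving.astype(float), com_field) > 0.5
    if np.logical_and(moving_aligned, fixed).any():
        smooth_px = 1.0
        fixed_img = _mask_to_sitk(fixed, smooth_px)
        moving_img = _mask_to_sitk(moving_aligned, smooth_px)
        demons = sitk.DiffeomorphicDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iterations))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(float(smoothing_sigma))

        field_img = None
        for level in range(pyramid_levels - 1, -1, -1):
            factor = 2**level
            f_lvl = sitk.Shrink(fixed_img, [factor, factor]) if factor > 1 else fixed_img
            m_lvl = sitk.Shrink(moving_img, [factor, factor]) if factor > 1 else moving_img
            if field_img is None:
                field_img = sitk.Image(f_lvl.GetSize(), sitk.sitkVectorFloat64)
                field_img.CopyInformation(f_lvl)
            else:
                field_img = sitk.Resample(
                    field_img, f_lvl, sitk.Transform(), sitk.sitkLinear
                )
            field_img = demons.Execute(f_lvl, m_lvl, field_img)
        field_img = sitk.Resample(field_img, fixed_img, sitk.Transform(), sitk.sitkLinear)
        demons_field = sitk.GetArrayFromImage(field_img)  # (H, W, (x, y))
        refine = np.stack([demons_field[..., 1], demons_field[..., 0]], axis=-1)

        # Compose: fixed -> demons refinement -> center-of-mass shift.
        composed = np.empty_like(refine)
        for k in range(2):
            composed[..., k] = refine[..., k] + warp_image(
                com_field[..., k], refine
            )
        candidates.append(composed)
    else:
        logger.warning(
            "masks do not overlap after coarse alignment: returning best-effort field"
        )

    scores = [
        dice(warp_image(moving.astype(float), f) > 0.5, fixed) for f in candidates
    ]
    best = candidates[int(np.argmax(scores))]
    pre = dice(moving, fixed)
    assert max(scores) >= pre - 1e-12, "registration decreased mask Dice"
    return DisplacementField(field_mm=best * pixel_size_mm, pixel_size_mm=pixel_size_mm)


@dataclass
class ROIRecord:
    row0: int
    col0: int
    size_px: int
    mean_cd31: float
    hvd_fraction: float
    tumor_pixels: int


@dataclass
class GridCorrelationResult:
    rois: list[ROIRecord]
    r: float
    p: float
    n: int


def grid_correlation(
    cd31: np.ndarray,
    labels_slice: np.ndarray,
    pixel_size_mm: float,
    roi_mm: float = 1.0,
) -> GridCorrelationResult:
    """Correlate mean CD31 intensity with HVD pixel fraction on a 1 mm grid.

    The tumor bounding box is tiled with non-overlapping ``roi_mm`` square
    ROIs anchored at the box origin; ROIs containing at least one tumor
    pixel contribute (sum CD31 / ROI pixel count, HVD pixels / ROI pixel
    count). ``labels_slice`` is a 2D cross-section of region labels.
    """
    cd31 = np.asarray(cd31, dtype=float)
    labels_slice = np.asarray(labels_slice)
    if cd31.shape != labels_slice.shape:
        raise ValueError("CD31 image and label slice must be co-registered (same shape)")
    size_px = int(round(roi_mm / pixel_size_mm))
    if size_px < 4:
        raise ValueError("ROI smaller than 4 pixels: decrease pixel size or enlarge ROI")

    tumor = labels_slice != LABEL_BACKGROUND
    if not tumor.any():
        raise ValueError("label slice contains no tumor pixels")
    rows = np.where(tumor.any(axis=1))[0]
    cols = np.where(tumor.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1

    records = []
    for rr in range(r0, r1, size_px):
        for cc in range(c0, c1, size_px):
            box = (slice(rr, min(rr + size_px, cd31.shape[0])),
                   slice(cc, min(cc + size_px, cd31.shape[1])))
            tpx = int(tumor[box].sum())
            if tpx == 0:
                continue
            npx = size_px * size_px  # full-ROI denominator
            records.append(
                ROIRecord(
                    row0=rr,
                    col0=cc,
                    size_px=size_px,
                    mean_cd31=float(cd31[box].sum()) / npx,
                    hvd_fraction=float((labels_slice[box] == LABEL_HVD).sum()) / npx,
                    tumor_pixels=tpx,
                )
            )
    if len(records) < 3:
        raise ValueError(f"only {len(records)} qualifying ROIs; need at least 3")
    x = np.array([rec.mean_cd31 for rec in records])
    y = np.array([rec.hvd_fraction for rec in records])
    r, p = pearson_correlation(x, y)
    return GridCorrelationResult(rois=records, r=r, p=p, n=len(records))


def positivity_ratio(
    numerator: np.ndarray, denominator: np.ndarray, tumor: np.ndarray
) -> float:
    """Ratio of positive pixel counts inside the tumor mask.

    Serves the Ki-67 index (Ki-67+/DAPI+), the vascular normalization
    index (aSMA+/CD31+), and the perfusion ratio (TL+/CD31+). The ratio
    may exceed 1 when the numerator stain is not a subset of the
    denominator stain.
    """
    numerator = np.asarray(numerator, dtype=bool)
    denominator = np.asarray(denominator, dtype=bool)
    tumor = np.asarray(tumor, dtype=bool)
    den = int((denominator & tumor).sum())
    if den == 0:
        raise ValueError("denominator stain has no positive pixels inside the tumor")
    return int((numerator & tumor).sum()) / den


def downsample_mean(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling (intensity-preserving) by an integer factor."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    h2, w2 = h // factor * factor, w // factor * factor
    return image[:h2, :w2].reshape(h2 // factor, factor, w2 // factor, factor).mean(axis=(1, 3))
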