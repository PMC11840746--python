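"""HbT noise-floor estimation and the avascular (AV) exclusion mask.

The noise threshold is learned from background regions: per frame, the
mean HbT over two rectangular ROIs; per volume, the mean over frames; per
subject, the maximum over that subject's volumes (timepoints); pooled, the
mean over subjects, rounded half-even to four decimal places on the a.u.
scale. Tumor voxels whose HbT falls strictly below the threshold are
avascular: their StO2 is zeroed and excluded from every later statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import HbTVolume, StO2Volume

__all__ = ["ROISpec", "NoiseEstimate", "estimate_noise_threshold", "apply_noise_threshold"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROISpec:
    """Frame-wise background rectangle: (axial, lateral) origin and size."""

    row: int
    col: int
    height: int = 50
    width: int = 50

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.height), slice(
            self.col, self.col + self.width
        )


def default_roi_specs(frame_shape: tuple[int, int], size: int = 50) -> tuple[ROISpec, ROISpec]:
    """Two ROIs in the shallow (low-axial) corners of each frame."""
    rows, cols = frame_shape
    size = min(size, rows, cols // 2)
    if size < 1:
        raise ValueError(f"frame shape {frame_shape} too small for background ROIs")
    return (ROISpec(0, 0, size, size), ROISpec(0, cols - size, size, size))


@dataclass
class NoiseEstimate:
    """Pooled HbT noise threshold with its per-subject provenance."""

    per_subject_max: dict[str, float]
    pooled_threshold: float
    roi_specs: tuple[ROISpec, ROISpec] = field(default=None)


def _volume_background_mean(hbt: HbTVolume, rois: tuple[ROISpec, ROISpec]) -> float:
    vals = hbt.values
    n_frames, n_rows, n_cols = vals.shape
    frame_means = np.empty(n_frames)
    for spec in rois:
        if (
            spec.row < 0
            or spec.col < 0
            or spec.row + spec.height > n_rows
            or spec.col + spec.width > n_cols
        ):
            raise ValueError(f"background ROI {spec} is out of frame bounds")
    for k in range(n_frames):
        pix = np.concatenate(
            [vals[k][spec.slices()].ravel() for spec in rois]
        )
        frame_means[k] = pix.mean()
    return float(frame_means.mean())


def estimate_noise_threshold(
    hbt_by_subject: dict[str, list[HbTVolume]],
    roi_specs: tuple[ROISpec, ROISpec] | None = None,
    tumor_masks: dict[str, list[np.ndarray]] | None = None,
) -> NoiseEstimate:
    """Pool a generalized HbT noise threshold across subjects.

    ``hbt_by_subject`` maps subject id to that subject's HbT volumes over
    timepoints. If ``tumor_masks`` is given, an ROI overlapping the tumor
    triggers a warning (background ROIs should be tumor-free) but does not
    abort.
    """
    if not hbt_by_subject:
        raise ValueError("need at least one subject")
    per_subject_max: dict[str, float] = {}
    rois_used = roi_specs
    for subject, volumes in hbt_by_subject.items():
        if not volumes:
            raise ValueError(f"subject {subject} has no HbT volumes")
        means = []
        for i, hbt in enumerate(volumes):
            rois = rois_used
            if rois is None:
                rois = default_roi_specs(hbt.values.shape[1:])
            if tumor_masks is not None:
                mask = tumor_masks[subject][i]
                for spec in rois:
                    if mask[:, spec.slices()[0], spec.slices()[1]].any():
                        logger.warning(
                            "background ROI %s overlaps the tumor mask for %s",
                            spec,
                            subject,
                        )
            means.append(_volume_background_mean(hbt, rois))
            rois_used = rois_used or rois
        per_subject_max[subject] = float(max(means))
    pooled = float(np.round(np.mean(list(per_subject_max.values())), 4))
    return NoiseEstimate(
        per_subject_max=per_subject_max,
        pooled_threshold=pooled,
        roi_specs=rois_used,
    )


def apply_noise_threshold(
    sto2: StO2Volume,
    hbt: HbTVolume,
    tumor: np.ndarray,
    threshold: float,
) -> tuple[StO2Volume, np.ndarray]:
    """Zero out sub-threshold tumor voxels and return the AV mask.

    A tumor voxel is avascular iff its HbT is strictly below ``threshold``;
    its StO2 is set to zero and flagged invalid so it never enters a
    regional mean.
    """
    if threshold < 0:
        raise ValueError("noise threshold must be >= 0")
    tumor = np.asarray(tumor, dtype=bool)
    sto2.grid.check_compatible(tumor, "tumor mask")
    sto2.grid.check_compatible(hbt.values, "HbT")
    av = tumor & (hbt.values < threshold)
    values = sto2.values.copy()
    valid = sto2.valid.copy()
    values[av] = 0.0
    valid[av] = False
    return (
        StO2Volume(grid=sto2.grid, values=values, valid=valid, scale=sto2.scale),
        av,
    )
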