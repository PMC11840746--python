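"""End-to-end orchestration: PA volumes in, regional labels and summaries out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import denoising, segmentation, unmixing
from .regional import RegionalSummary, summarize_regions
from .types import (
    ExtinctionTable,
    FluenceMap,
    HbTVolume,
    PAVolumeSet,
    RegionLabelVolume,
    RunConfig,
    StO2Volume,
)

__all__ = ["VRAResult", "run_vra", "run_longitudinal"]


@dataclass
class VRAResult:
    sto2: StO2Volume
    hbt: HbTVolume
    labels: RegionLabelVolume
    noise_threshold: float
    otsu_threshold: float
    summary: RegionalSummary | None = None


def run_vra(
    pa: PAVolumeSet,
    tumor: np.ndarray,
    eps: ExtinctionTable,
    fluence: dict[float, FluenceMap] | None = None,
    noise_threshold: float | str = "auto",
    config: RunConfig | None = None,
    noise_rois=None,
    subject: str = "",
    timepoint: str = "",
) -> VRAResult:
    """Unmix, denoise, segment, and summarize one acquisition.

    ``noise_threshold="auto"`` estimates the HbT noise floor from
    background ROIs of this single volume; for the pooled multi-subject
    estimate run :func:`vra.denoising.estimate_noise_threshold` first and
    pass the number.
    """
    config = config or RunConfig()
    if fluence is not None:
        pa = unmixing.apply_fluence_compensation(pa, fluence)
    maps = unmixing.unmix_nnls(pa, eps)
    sto2 = unmixing.compute_sto2(maps, scale=config.sto2_scale)
    hbt = unmixing.compute_hbt(maps)

    if noise_threshold == "auto":
        est = denoising.estimate_noise_threshold(
            {"_self": [hbt]}, roi_specs=noise_rois
        )
        threshold = est.pooled_threshold
    else:
        threshold = float(noise_threshold)
    sto2, av = denoising.apply_noise_threshold(sto2, hbt, tumor, threshold)

    normalized = segmentation.normalize_unit(hbt)
    filtered = segmentation.gaussian_highpass_3d(
        normalized, pa.grid, cutoff_fraction=config.hp_cutoff_fraction
    )
    labels, otsu_t = segmentation.segment_regions(filtered, tumor, av, pa.grid)
    summary = summarize_regions(sto2, hbt, labels, subject=subject, timepoint=timepoint)
    return VRAResult(
        sto2=sto2,
        hbt=hbt,
        labels=labels,
        noise_threshold=threshold,
        otsu_threshold=otsu_t,
        summary=summary,
    )


def run_longitudinal(
    series: list[dict],
    eps: ExtinctionTable,
    config: RunConfig | None = None,
    noise_rois=None,
    subject: str = "S1",
) -> list[VRAResult]:
    """Run the pipeline over a longitudinal series (one subject).

    The noise threshold is pooled over the subject's timepoints (maximum
    of per-volume background means), matching the acquisition-wide
    thresholding procedure.
    """
    config = config or RunConfig()
    hbts = []
    prepped = []
    for rec in series:
        pa = unmixing.apply_fluence_compensation(rec["pa"], rec["fluence"])
        maps = unmixing.unmix_nnls(pa, eps)
        sto2 = unmixing.compute_sto2(maps, scale=config.sto2_scale)
        hbt = unmixing.compute_hbt(maps)
        hbts.append(hbt)
        prepped.append((rec, sto2, hbt))
    est = denoising.estimate_noise_threshold({subject: hbts}, roi_specs=noise_rois)
    threshold = est.pooled_threshold

    results = []
    for rec, sto2, hbt in prepped:
        sto2, av = denoising.apply_noise_threshold(sto2, hbt, rec["tumor"], threshold)
        normalized = segmentation.normalize_unit(hbt)
        filtered = segmentation.gaussian_highpass_3d(
            normalized, hbt.grid, cutoff_fraction=config.hp_cutoff_fraction
        )
        labels, otsu_t = segmentation.segment_regions(
            filtered, rec["tumor"], av, hbt.grid
        )
        summary = summarize_regions(
            sto2, hbt, labels, subject=subject, timepoint=rec["timepoint"]
        )
        results.append(
            VRAResult(
                sto2=sto2,
                hbt=hbt,
                labels=labels,
                noise_threshold=threshold,
                otsu_threshold=otsu_t,
                summary=summary,
            )
        )
    return results
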