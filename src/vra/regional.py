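"""Per-region summaries and longitudinal treatment-response metrics.

Regional StO2 means are computed over valid voxels only (avascular and
otherwise-invalid voxels were "omitted from further analysis" upstream);
the whole-tumor HbT mean includes every tumor voxel, since avascularity is
itself defined from HbT. Deltas are later minus earlier, with StO2 deltas
expressed in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan

import numpy as np
import pandas as pd
from scipy import stats

from .types import HbTVolume, RegionLabelVolume, StO2Volume

__all__ = [
    "RegionalSummary",
    "DeltaMetrics",
    "summarize_regions",
    "delta_metrics",
    "pearson_correlation",
    "longitudinal_table",
]

REGIONS = ("HVD", "LVD", "tumor")


@dataclass
class RegionStats:
    mean_sto2: float  # nan when the region has no valid voxels
    mean_hbt: float
    voxel_count: int


@dataclass
class RegionalSummary:
    subject: str
    timepoint: str
    regions: dict[str, RegionStats]
    hvd_fraction: float
    lvd_fraction: float
    av_fraction: float
    tumor_voxels: int


@dataclass
class DeltaMetrics:
    subject: str
    pair: str  # e.g. "D(-1):D(3)"
    delta_sto2: dict[str, float]  # per region, pp; nan when undefined
    delta_hbt: dict[str, float]


def _region_stats(
    sto2: StO2Volume, hbt: HbTVolume, region_mask: np.ndarray, hbt_all: bool = False
) -> RegionStats:
    n = int(region_mask.sum())
    valid = region_mask & sto2.valid
    mean_sto2 = float(sto2.values[valid].mean()) if valid.any() else nan
    hbt_mask = region_mask if hbt_all else (region_mask & hbt.valid)
    mean_hbt = float(hbt.values[hbt_mask].mean()) if hbt_mask.any() else nan
    return RegionStats(mean_sto2=mean_sto2, mean_hbt=mean_hbt, voxel_count=n)


def summarize_regions(
    sto2: StO2Volume,
    hbt: HbTVolume,
    labels: RegionLabelVolume,
    subject: str = "",
    timepoint: str = "",
) -> RegionalSummary:
    """Means and fractions per region for one (subject, timepoint) volume."""
    sto2.grid.check_compatible(labels.labels, "label volume")
    tumor = labels.tumor
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("labels contain no tumor voxels")
    regions = {
        "HVD": _region_stats(sto2, hbt, labels.hvd),
        "LVD": _region_stats(sto2, hbt, labels.lvd),
        "tumor": _region_stats(sto2, hbt, tumor, hbt_all=True),
    }
    return RegionalSummary(
        subject=subject,
        timepoint=timepoint,
        regions=regions,
        hvd_fraction=int(labels.hvd.sum()) / n_tumor,
        lvd_fraction=int(labels.lvd.sum()) / n_tumor,
        av_fraction=int(labels.av.sum()) / n_tumor,
        tumor_voxels=n_tumor,
    )


def delta_metrics(earlier: RegionalSummary, later: RegionalSummary) -> DeltaMetrics:
    """Componentwise later - earlier regional means for one subject."""
    if earlier.subject != later.subject:
        raise ValueError(
            f"subject mismatch: {earlier.subject!r} vs {later.subject!r}"
        )
    d_sto2 = {}
    d_hbt = {}
    for region in REGIONS:
        a, b = earlier.regions[region], later.regions[region]
        d_sto2[region] = b.mean_sto2 - a.mean_sto2  # nan propagates as "undefined"
        d_hbt[region] = b.mean_hbt - a.mean_hbt
    return DeltaMetrics(
        subject=earlier.subject,
        pair=f"{earlier.timepoint}:{later.timepoint}",
        delta_sto2=d_sto2,
        delta_hbt=d_hbt,
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with a two-tailed p from the t-distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def longitudinal_table(
    summaries: list[RegionalSummary],
    delta_pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialize summaries (and requested deltas) as tidy tables.

    Returns ``(summary_df, delta_df)`` with one summary row per
    (subject, timepoint, region). Requested delta pairs missing a
    timepoint for a subject are emitted with ``defined=False``.
    """
    seen = set()
    rows = []
    for s in summaries:
        key = (s.subject, s.timepoint)
        if key in seen:
            raise ValueError(f"duplicate (subject, timepoint) rows: {key}")
        seen.add(key)
        for region in REGIONS:
            st = s.regions[region]
            rows.append(
                {
                    "subject": s.subject,
                    "timepoint": s.timepoint,
                    "region": region,
                    "mean_sto2": st.mean_sto2,
                    "mean_hbt": st.mean_hbt,
                    "voxel_count": st.voxel_count,
                    "hvd_fraction": s.hvd_fraction,
                    "lvd_fraction": s.lvd_fraction,
                    "av_fraction": s.av_fraction,
                }
            )
    summary_df = pd.DataFrame(rows)

    delta_rows = []
    if delta_pairs:
        by_subject: dict[str, dict[str, RegionalSummary]] = {}
        for s in summaries:
            by_subject.setdefault(s.subject, {})[s.timepoint] = s
        for subject, tps in by_subject.items():
            for t0, t1 in delta_pairs:
                if t0 in tps and t1 in tps:
                    d = delta_metrics(tps[t0], tps[t1])
                    for region in REGIONS:
                        delta_rows.append(
                            {
                                "subject": subject,
                                "pair": d.pair,
                                "region": region,
                                "delta_sto2": d.delta_sto2[region],
                                "delta_hbt": d.delta_hbt[region],
                                "defined": True,
                            }
                        )
                else:
                    for region in REGIONS:
                        delta_rows.append(
                            {
                                "subject": subject,
                                "pair": f"{t0}:{t1}",
                                "region": region,
                                "delta_sto2": nan,
                                "delta_hbt": nan,
                                "defined": False,
                            }
                        )
    delta_df = pd.DataFrame(
        delta_rows,
        columns=["subject", "pair", "region", "delta_sto2", "delta_hbt", "defined"],
    )
    return summary_df, delta_df
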