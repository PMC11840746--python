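"""Core containers for volumetric photoacoustic data.

Conventions
-----------
Volumes are indexed ``(frame, axial, lateral)``, 0-based, voxel centers.
All physical lengths are millimetres; wavelengths are nanometres; PA
intensities and hemoglobin concentrations are in arbitrary units (a.u.).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "PAVolumeSet",
    "FluenceMap",
    "ExtinctionTable",
    "ChromophoreMaps",
    "StO2Volume",
    "HbTVolume",
    "RegionLabelVolume",
    "IFImage",
    "RunConfig",
    "AXIS_NAMES",
    "LABEL_BACKGROUND",
    "LABEL_AV",
    "LABEL_LVD",
    "LABEL_HVD",
]

AXIS_NAMES = ("elevational", "axial", "lateral")

#: Region labels used throughout the pipeline (uint8 volumes on disk).
LABEL_BACKGROUND = 0
LABEL_AV = 1
LABEL_LVD = 2
LABEL_HVD = 3


@dataclass(frozen=True)
class VoxelGrid:
    """Shape and anisotropic voxel spacing of a 3D scan.

    Default spacing matches a linear-array photoacoustic scan stepped
    0.150 mm elevationally with 75 um axial and 165 um lateral resolution.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.150, 0.075, 0.165)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("VoxelGrid is strictly three-dimensional")
        for name, n in zip(AXIS_NAMES, self.shape):
            if int(n) < 1:
                raise ValueError(f"{name} extent must be >= 1, got {n}")
        for name, s in zip(AXIS_NAMES, self.spacing):
            if not np.isfinite(s) or s <= 0:
                raise ValueError(f"{name} spacing must be > 0, got {s}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers along each axis."""
        return tuple(
            (np.arange(n) + 0.5) * s for n, s in zip(self.shape, self.spacing)
        )

    def check_compatible(self, arr: np.ndarray, what: str = "volume") -> None:
        if tuple(arr.shape) != self.shape:
            raise ValueError(
                f"{what} shape {tuple(arr.shape)} does not match grid {self.shape}"
            )


def _require_finite(arr: np.ndarray, what: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"{what} contains a non-finite voxel at index {idx}")


@dataclass
class PAVolumeSet:
    """Per-wavelength PA intensity volumes P(lambda) on a shared grid."""

    grid: VoxelGrid
    volumes: dict[float, np.ndarray]
    valid: np.ndarray | None = None  # True where the voxel is usable

    def __post_init__(self) -> None:
        if not self.volumes:
            raise ValueError("PAVolumeSet needs at least one wavelength")
        vols = {}
        for wl, vol in self.volumes.items():
            vol = np.asarray(vol, dtype=float)
            self.grid.check_compatible(vol, f"PA volume at {wl} nm")
            _require_finite(vol, f"PA volume at {wl} nm")
            vols[float(wl)] = vol
        self.volumes = vols
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            self.grid.check_compatible(self.valid, "validity mask")

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.volumes))


@dataclass
class FluenceMap:
    """Optical fluence F(lambda) on the scan grid; strictly positive."""

    grid: VoxelGrid
    wavelength: float
    volume: np.ndarray

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.grid.check_compatible(self.volume, "fluence map")
        _require_finite(self.volume, "fluence map")
        if (self.volume <= 0).any():
            raise ValueError("fluence must be strictly positive everywhere")


class ExtinctionTable:
    """Molar extinction coefficients eps(lambda) for Hb and HbO2.

    Units are cm^-1 M^-1. The 2x2 system matrix for any requested
    wavelength pair must be non-singular.
    """

    def __init__(self, entries: Mapping[float, tuple[float, float]]):
        self._entries: dict[float, tuple[float, float]] = {}
        for wl, (eps_hb, eps_hbo2) in entries.items():
            wl = float(wl)
            if wl in self._entries:
                raise ValueError(f"duplicate wavelength {wl} nm in extinction table")
            if eps_hb <= 0 or eps_hbo2 <= 0:
                raise ValueError(f"extinction coefficients at {wl} nm must be > 0")
            self._entries[wl] = (float(eps_hb), float(eps_hbo2))
        if not self._entries:
            raise ValueError("extinction table is empty")

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self._entries))

    def lookup(self, wavelength: float) -> tuple[float, float]:
        """Return (eps_Hb, eps_HbO2) at an exact tabulated wavelength."""
        wl = float(wavelength)
        if wl not in self._entries:
            raise KeyError(f"wavelength {wl} nm not present in extinction table")
        return self._entries[wl]

    def matrix(self, wavelengths: Sequence[float]) -> np.ndarray:
        """System matrix with one row per wavelength, columns (Hb, HbO2)."""
        E = np.array([self.lookup(wl) for wl in wavelengths], dtype=float)
        if E.shape[0] == 2:
            det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
            scale = np.abs(E).max() ** 2
            if abs(det) < 1e-12 * scale:
                raise ValueError(
                    f"extinction matrix for wavelengths {tuple(wavelengths)} is singular"
                )
        return E


@dataclass
class ChromophoreMaps:
    """Voxelwise Hb and HbO2 concentrations (a.u.) from spectral unmixing."""

    grid: VoxelGrid
    c_hb: np.ndarray
    c_hbo2: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.c_hb = np.asarray(self.c_hb, dtype=float)
        self.c_hbo2 = np.asarray(self.c_hbo2, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        for name, arr in (("C_Hb", self.c_hb), ("C_HbO2", self.c_hbo2)):
            self.grid.check_compatible(arr, name)
            _require_finite(arr[self.valid], name)
            if (arr[self.valid] < 0).any():
                raise ValueError(f"{name} must be non-negative on valid voxels")


@dataclass
class StO2Volume:
    """Blood oxygen saturation map; invalid voxels are excluded from means."""

    grid: VoxelGrid
    values: np.ndarray
    valid: np.ndarray
    scale: str = "percent"  # or "fraction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.grid.check_compatible(self.values, "StO2")
        self.grid.check_compatible(self.valid, "StO2 validity mask")
        if self.scale not in ("percent", "fraction"):
            raise ValueError("scale must be 'percent' or 'fraction'")
        hi = 100.0 if self.scale == "percent" else 1.0
        v = self.values[self.valid]
        if v.size and ((v < -1e-9).any() or (v > hi + 1e-9).any()):
            raise ValueError(f"StO2 outside [0, {hi}] on valid voxels")


@dataclass
class HbTVolume:
    """Total hemoglobin signal HbT = C_Hb + C_HbO2 (a.u.)."""

    grid: VoxelGrid
    values: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid.check_compatible(self.values, "HbT")
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            self.grid.check_compatible(self.valid, "HbT validity mask")
        v = self.values[self.valid]
        _require_finite(v, "HbT")
        if v.size and (v < 0).any():
            raise ValueError("HbT must be non-negative on valid voxels")


@dataclass
class RegionLabelVolume:
    """Per-voxel region labels: background=0, AV=1, LVD=2, HVD=3.

    Non-background labels exactly tile the tumor mask.
    """

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.grid.check_compatible(self.labels, "label volume")
        if self.labels.max(initial=0) > LABEL_HVD:
            raise ValueError("labels must be in {0: background, 1: AV, 2: LVD, 3: HVD}")

    @property
    def tumor(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND

    @property
    def av(self) -> np.ndarray:
        return self.labels == LABEL_AV

    @property
    def lvd(self) -> np.ndarray:
        return self.labels == LABEL_LVD

    @property
    def hvd(self) -> np.ndarray:
        return self.labels == LABEL_HVD

    def assert_partition(self, tumor_mask: np.ndarray) -> None:
        """The Eq.-10-style identity |HVD| + |LVD| + |AV| = |tumor|."""
        if not np.array_equal(self.tumor, np.asarray(tumor_mask, dtype=bool)):
            raise AssertionError("region labels do not tile the tumor mask")


@dataclass
class IFImage:
    """Named immunofluorescence channels sharing one 2D shape."""

    channels: dict[str, np.ndarray]
    pixel_size_mm: float

    KNOWN = ("DAPI", "CD31", "aSMA", "TL", "Ki67")

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel size must be > 0")
        if not self.channels:
            raise ValueError("IFImage needs at least one channel")
        shapes = set()
        chans = {}
        for name, img in self.channels.items():
            img = np.asarray(img, dtype=float)
            if img.ndim != 2:
                raise ValueError(f"channel {name} must be 2D")
            if (img < 0).any():
                raise ValueError(f"channel {name} must be non-negative")
            shapes.add(img.shape)
            chans[name] = img
        if len(shapes) != 1:
            raise ValueError("all IF channels must share one shape")
        self.channels = chans

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class RunConfig:
    """Run-level configuration shared by the CLI entry points."""

    noise_threshold: float | str = "auto"
    hp_cutoff_fraction: float = 0.02
    grid_roi_mm: float = 1.0
    sto2_scale: str = "percent"
    random_seed: int = 0
    fluence_floor_rel: float = 1e-6

    def __post_init__(self) -> None:
        if self.noise_threshold != "auto" and float(self.noise_threshold) < 0:
            raise ValueError("noise_threshold must be >= 0 or 'auto'")
        if not (0 < self.hp_cutoff_fraction <= 1):
            raise ValueError("hp_cutoff_fraction must be in (0, 1]")
        if self.grid_roi_mm <= 0:
            raise ValueError("grid_roi_mm must be > 0")
        if self.sto2_scale not in ("percent", "fraction"):
            raise ValueError("sto2_scale must be 'percent' or 'fraction'")
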