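"""Readers and writers for volumes, masks, IF channels, and extinction tables.

Supported volume containers are multi-page TIFF (one page per elevational
frame) and NIfTI-1. TIFF has no canonical three-axis spacing, so spacing
travels in a JSON sidecar ``{"spacing_mm": [e, a, l], "wavelength_nm": w}``;
for NIfTI the header zooms win over any sidecar. Absence of every spacing
source is an error, never a silent default.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AXIS_NAMES, ExtinctionTable, VoxelGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_image_2d",
    "load_extinction_table",
    "default_sidecar_path",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def default_sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _load_sidecar(sidecar_path: Path) -> dict:
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    spacing = meta.get("spacing_mm")
    if spacing is not None:
        if len(spacing) != 3:
            raise ValueError("sidecar spacing_mm must have three entries")
        for name, s in zip(AXIS_NAMES, spacing):
            if not np.isfinite(s) or s <= 0:
                raise ValueError(
                    f"sidecar spacing_mm has non-positive {name} entry: {s}"
                )
    return meta


def read_volume(
    path: str | Path, sidecar_path: str | Path | None = None
) -> tuple[np.ndarray, VoxelGrid, dict]:
    """Read a 3D volume with its voxel spacing.

    Returns ``(array, grid, meta)`` where ``meta`` carries any sidecar
    fields (e.g. ``wavelength_nm``). For NIfTI the header zooms define the
    spacing; for TIFF the sidecar is mandatory (defaulting to
    ``<path>.json`` when present on disk).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    meta: dict = {}
    if sidecar_path is None:
        candidate = default_sidecar_path(path)
        sidecar_path = candidate if candidate.exists() else None
    if sidecar_path is not None:
        meta = _load_sidecar(Path(sidecar_path))

    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI volume, got ndim={arr.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            arr = arr[None, ...]
        if arr.ndim != 3:
            raise ValueError(f"expected a multi-page TIFF volume, got ndim={arr.ndim}")
        spacing = meta.get("spacing_mm")
        if spacing is None:
            raise ValueError(
                f"TIFF volume {path} has no spacing: provide a JSON sidecar"
            )
        spacing = tuple(float(s) for s in spacing)
    else:
        raise ValueError(f"unsupported volume container: {path.suffix!r}")

    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        bad = ~np.isfinite(arr)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"volume {path} has a non-finite voxel at {idx}")
    grid = VoxelGrid(shape=tuple(arr.shape), spacing=spacing)
    return arr, grid, meta


def write_volume(
    arr: np.ndarray,
    grid: VoxelGrid,
    path: str | Path,
    sidecar_path: str | Path | None = None,
    wavelength_nm: float | None = None,
) -> Path:
    """Write a volume; the inverse of :func:`read_volume`.

    Integer data round-trips bitwise; floats are stored at full 64-bit
    precision. For TIFF a JSON sidecar (``<path>.json`` by default) records
    the spacing.
    """
    arr = np.asarray(arr)
    if arr.ndim != 3 or 0 in arr.shape:
        raise ValueError(f"can only write non-empty 3D volumes, got shape {arr.shape}")
    grid.check_compatible(arr)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag(list(grid.spacing) + [1.0])
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms(grid.spacing)
        nib.save(img, str(path))
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        if np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64, copy=False)
        tifffile.imwrite(str(path), arr, photometric="minisblack")
        if sidecar_path is None:
            sidecar_path = default_sidecar_path(path)
    else:
        raise ValueError(f"unsupported volume container: {path.suffix!r}")

    if sidecar_path is not None:
        meta = {"spacing_mm": list(grid.spacing)}
        if wavelength_nm is not None:
            meta["wavelength_nm"] = float(wavelength_nm)
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh)
    return path


def read_image_2d(path: str | Path) -> np.ndarray:
    """Read a single-plane TIFF/PNG image as a float 2D array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        img = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        img = iio.imread(str(path))
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # collapse RGB(A) to luminance
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image in {path}, got ndim={img.ndim}")
    return img


def load_extinction_table(source: str | Path | None = None) -> ExtinctionTable:
    """Load molar extinction coefficients for Hb and HbO2.

    ``source=None`` loads the packaged table (680-970 nm, 10 nm steps,
    compiled from the standard tabulated hemoglobin spectra). A user CSV
    must provide columns ``wavelength_nm, eps_Hb, eps_HbO2``.
    """
    if source is None:
        with resources.files("vra.data").joinpath("hb_extinction.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source)
    cols = {c.lower(): c for c in df.columns}
    try:
        wl_col = cols.get("wavelength_nm") or cols["wavelength"]
        hb_col = cols["eps_hb"]
        hbo2_col = cols["eps_hbo2"]
    except KeyError as exc:
        raise ValueError(
            "extinction CSV needs columns wavelength_nm, eps_Hb, eps_HbO2"
        ) from exc
    wls = df[wl_col].astype(float)
    if wls.duplicated().any():
        dup = wls[wls.duplicated()].iloc[0]
        raise ValueError(f"duplicate wavelength {dup} nm in extinction table")
    entries = {
        float(row[wl_col]): (float(row[hb_col]), float(row[hbo2_col]))
        for _, row in df.iterrows()
    }
    return ExtinctionTable(entries)
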