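"""Fluence compensation and two-wavelength spectral unmixing.

The photoacoustic signal at wavelength lambda is modeled as

    P(lambda) = F(lambda) * (eps_Hb(lambda) C_Hb + eps_HbO2(lambda) C_HbO2)

up to a global constant (Grueneisen parameter and heat-conversion fraction
are absorbed into the arbitrary unit scale). After dividing out the
fluence, each voxel is unmixed by non-negative least squares:

    (C_Hb, C_HbO2) = argmin_{c >= 0} || E c - p ||_2

with E the 2x2 extinction matrix. For two wavelengths this has a closed
form: take the unconstrained solve if it is non-negative, otherwise clamp
each component to zero in turn, re-solve the one-variable problem, and keep
the lower-residual corner.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    ChromophoreMaps,
    ExtinctionTable,
    FluenceMap,
    HbTVolume,
    PAVolumeSet,
    StO2Volume,
)

__all__ = [
    "apply_fluence_compensation",
    "unmix_nnls",
    "nnls_2x2",
    "compute_sto2",
    "compute_hbt",
]

logger = logging.getLogger(__name__)

#: Negative intensities larger (in magnitude) than this fraction of the
#: volume maximum abort the run; smaller ones are clipped to zero.
NEGATIVE_TOLERANCE_REL = 1e-9


def apply_fluence_compensation(
    pa: PAVolumeSet,
    fluence: dict[float, FluenceMap],
    floor: float | None = None,
) -> PAVolumeSet:
    """Divide each PA volume by its fluence map.

    Voxels where the fluence falls below ``floor`` (default ``1e-6`` times
    the map maximum) are never divided; they are marked invalid and the
    invalidity propagates through unmixing and all downstream statistics.
    """
    compensated: dict[float, np.ndarray] = {}
    valid = pa.valid.copy()
    for wl in pa.wavelengths:
        if wl not in fluence:
            raise KeyError(f"no fluence map provided for {wl} nm")
        fmap = fluence[wl]
        pa.grid.check_compatible(fmap.volume, f"fluence map at {wl} nm")
        f = fmap.volume
        wl_floor = 1e-6 * float(f.max()) if floor is None else float(floor)
        if wl_floor <= 0:
            raise ValueError("fluence floor must be > 0")
        ok = f >= wl_floor
        out = np.zeros_like(pa.volumes[wl])
        np.divide(pa.volumes[wl], f, out=out, where=ok)
        compensated[wl] = out
        valid &= ok
    return PAVolumeSet(grid=pa.grid, volumes=compensated, valid=valid)


def nnls_2x2(E: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closed-form non-negative least squares for a 2x2 system.

    ``p`` has shape ``(..., 2)``; the result has the same shape with
    components ``(C_Hb, C_HbO2)``.
    """
    E = np.asarray(E, dtype=float)
    if E.shape != (2, 2):
        raise ValueError("E must be 2x2")
    det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
    if abs(det) < 1e-12 * max(np.abs(E).max() ** 2, 1e-300):
        raise ValueError("extinction matrix is singular")

    p = np.asarray(p, dtype=float)
    # Unconstrained solve.
    c0 = (E[1, 1] * p[..., 0] - E[0, 1] * p[..., 1]) / det
    c1 = (E[0, 0] * p[..., 1] - E[1, 0] * p[..., 0]) / det
    c = np.stack([c0, c1], axis=-1)

    interior = (c0 >= 0) & (c1 >= 0)
    if interior.all():
        return c

    # Single-variable solves along each non-negative axis.
    cols = E.T  # cols[j] is the j-th column of E
    corners = []
    residuals = []
    for j in range(2):
        a = cols[j]
        coef = np.maximum((p @ a) / (a @ a), 0.0)
        r = p - coef[..., None] * a
        corners.append(coef)
        residuals.append(np.einsum("...i,...i->...", r, r))
    pick1 = residuals[1] < residuals[0]
    corner = np.zeros_like(c)
    corner[..., 0] = np.where(pick1, 0.0, corners[0])
    corner[..., 1] = np.where(pick1, corners[1], 0.0)
    return np.where(interior[..., None], c, corner)


def unmix_nnls(compensated: PAVolumeSet, eps: ExtinctionTable) -> ChromophoreMaps:
    """Per-voxel NNLS unmixing of a dual-wavelength PA set into Hb/HbO2."""
    wls = compensated.wavelengths
    if len(wls) != 2:
        raise ValueError(f"two-wavelength unmixing requires 2 wavelengths, got {len(wls)}")
    E = eps.matrix(wls)

    p = np.stack([compensated.volumes[wl] for wl in wls], axis=-1)
    vmax = np.abs(p).max()
    neg = p < 0
    if neg.any():
        worst = p.min()
        if worst < -NEGATIVE_TOLERANCE_REL * max(vmax, 1e-300):
            idx = tuple(int(i) for i in np.argwhere(p == worst)[0][:3])
            raise ValueError(
                f"negative PA intensity {worst:g} at voxel {idx} exceeds tolerance"
            )
        logger.info("clipped %d tiny negative intensities to zero", int(neg.sum()))
        p = np.where(neg, 0.0, p)

    c = nnls_2x2(E, p)
    valid = compensated.valid
    c[~valid] = 0.0
    return ChromophoreMaps(
        grid=compensated.grid, c_hb=c[..., 0], c_hbo2=c[..., 1], valid=valid
    )


def compute_sto2(maps: ChromophoreMaps, scale: str = "percent") -> StO2Volume:
    """StO2 = C_HbO2 / (C_Hb + C_HbO2); voxels with zero HbT are invalid."""
    hbt = maps.c_hb + maps.c_hbo2
    valid = maps.valid & (hbt > 0)
    values = np.zeros_like(hbt)
    np.divide(maps.c_hbo2, hbt, out=values, where=valid)
    if scale == "percent":
        values *= 100.0
    elif scale != "fraction":
        raise ValueError("scale must be 'percent' or 'fraction'")
    values[~valid] = 0.0
    return StO2Volume(grid=maps.grid, values=values, valid=valid, scale=scale)


def compute_hbt(maps: ChromophoreMaps) -> HbTVolume:
    """Total hemoglobin signal HbT = C_Hb + C_HbO2, voxelwise."""
    return HbTVolume(grid=maps.grid, values=maps.c_hb + maps.c_hbo2, valid=maps.valid)
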