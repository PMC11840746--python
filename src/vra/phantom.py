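"""Synthetic vessel-network tumor phantoms with known regional ground truth.

The phantom emulates the data the regional segmentation assumes: an
ellipsoidal tumor whose sub-regions differ in vessel density, drawn as
random straight-tube segments over a weak diffuse hemoglobin background
(sub-resolution capillary signal). Concentration maps are blurred by a
Gaussian acoustic point-spread function, so that densely vascularized
regions blur into a near-continuum of signal while sparse regions retain
isolated dim bumps -- the texture contrast the frequency-domain
segmentation exploits. Dual-wavelength PA volumes follow the forward
model

    P(lambda) = F(lambda, depth) * (eps_Hb C_Hb + eps_HbO2 C_HbO2) + noise

with a 1D exponential fluence decay F = exp(-mu_eff * depth) and additive
Gaussian noise clipped at zero (detected PA amplitudes are non-negative).
Per-voxel ground-truth StO2 and HbT are emitted from the final (blurred)
concentration fields, so that on a noiseless, fluence-free phantom the
unmixing chain recovers them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import load_extinction_table
from .types import ExtinctionTable, FluenceMap, IFImage, PAVolumeSet, VoxelGrid

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "TreatmentEffect",
    "two_region_spec",
    "default_sunitinib_effect",
    "generate_phantom",
    "generate_pseudo_histology",
    "generate_longitudinal_series",
    "block_fractions",
    "resample_slice",
]


@dataclass(frozen=True)
class RegionSpec:
    """A tumor sub-region with homogeneous vascular parameters.

    The region is the set of tumor voxels whose physical coordinate along
    ``axis`` lies in ``[lo_mm, hi_mm)`` (``None`` bounds are open).
    ``vessel_density`` is the expected number of vessel segments per mm^3;
    ``diffuse_hbt_frac`` is the diffuse (sub-resolution capillary) HbT as
    a fraction of the intravascular HbT amplitude.
    """

    name: str
    axis: int = 2
    lo_mm: float | None = None
    hi_mm: float | None = None
    vessel_density: float = 1.0  # segments per mm^3
    vessel_radius_mm: float = 0.12
    sto2_pct: float = 60.0
    diffuse_hbt_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.vessel_density < 0:
            raise ValueError("vessel density must be >= 0")
        if self.vessel_radius_mm <= 0:
            raise ValueError("vessel radius must be > 0")
        if not (0 <= self.sto2_pct <= 100):
            raise ValueError("StO2 must be in [0, 100]")
        if self.diffuse_hbt_frac < 0:
            raise ValueError("diffuse HbT fraction must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    grid: VoxelGrid
    tumor_center_mm: tuple[float, float, float]
    tumor_semiaxes_mm: tuple[float, float, float]
    regions: tuple[RegionSpec, ...]
    hbt_amplitude: float = 5e-3  # intravascular HbT, a.u.
    noise_sd: float = 0.1  # additive PA noise, a.u.
    mu_eff_per_mm: float = 0.3  # fluence decay coefficient
    psf_sigma_mm: float = 0.25  # acoustic point-spread (isotropic)
    vessel_length_mm: tuple[float, float] = (0.8, 1.6)
    wavelengths: tuple[float, float] = (750.0, 850.0)
    seed: int = 0


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside every simulated volume."""

    grid: VoxelGrid
    tumor_mask: np.ndarray
    vessel_mask: np.ndarray
    region_labels: np.ndarray  # -1 outside tumor, else index into region_names
    region_names: tuple[str, ...]
    sto2_pct: np.ndarray  # per-voxel truth (0 where HbT = 0)
    hbt: np.ndarray
    vascular_density: np.ndarray | None = None  # pre-PSF HbT (tubes + capillary background)
    vessel_volume_fraction: dict[str, float] = field(default_factory=dict)

    def region_mask(self, name: str) -> np.ndarray:
        return self.region_labels == self.region_names.index(name)


def two_region_spec(
    grid: VoxelGrid | None = None,
    dense_density: float = 5.0,
    sparse_density: float = 0.5,
    dense_sto2: float = 70.0,
    sparse_sto2: float = 45.0,
    seed: int = 0,
) -> PhantomSpec:
    """Default two-region phantom: dense and sparse lateral halves.

    The default grid (64 x 96 x 96 voxels at 0.150/0.075/0.165 mm) holds a
    roughly 180 mm^3 ellipsoidal tumor, comparable to the subcutaneous
    xenografts the pipeline is designed for.
    """
    if grid is None:
        grid = VoxelGrid(shape=(64, 96, 96))
    ext = grid.extent_mm
    center = (ext[0] / 2, ext[1] / 2, ext[2] / 2)
    semi = (0.34 * ext[0], 0.33 * ext[1], 0.35 * ext[2])
    split = center[2]
    regions = (
        RegionSpec(
            name="dense",
            axis=2,
            hi_mm=split,
            vessel_density=dense_density,
            vessel_radius_mm=0.12,
            sto2_pct=dense_sto2,
        ),
        RegionSpec(
            name="sparse",
            axis=2,
            lo_mm=split,
            vessel_density=sparse_density,
            vessel_radius_mm=0.08,
            sto2_pct=sparse_sto2,
        ),
    )
    return PhantomSpec(
        grid=grid,
        tumor_center_mm=center,
        tumor_semiaxes_mm=semi,
        regions=regions,
        seed=seed,
    )


def _ellipsoid_mask(grid: VoxelGrid, center, semiaxes) -> np.ndarray:
    ce, ca, cl = grid.coords_mm()
    E, A, L = np.meshgrid(ce, ca, cl, indexing="ij")
    return (
        ((E - center[0]) / semiaxes[0]) ** 2
        + ((A - center[1]) / semiaxes[1]) ** 2
        + ((L - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _region_masks(spec: PhantomSpec, tumor: np.ndarray) -> dict[str, np.ndarray]:
    coords = spec.grid.coords_mm()
    masks = {}
    for region in spec.regions:
        c = coords[region.axis]
        sel = np.ones(spec.grid.shape[region.axis], dtype=bool)
        if region.lo_mm is not None:
            sel &= c >= region.lo_mm
        if region.hi_mm is not None:
            sel &= c < region.hi_mm
        shape = [1, 1, 1]
        shape[region.axis] = -1
        masks[region.name] = tumor & sel.reshape(shape)
    return masks


def _sample_vessels(
    spec: PhantomSpec,
    region: RegionSpec,
    region_mask: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random line segments (endpoints in mm) centered inside the region."""
    voxel_vol = float(np.prod(spec.grid.spacing))
    volume_mm3 = float(region_mask.sum()) * voxel_vol
    n = int(rng.poisson(region.vessel_density * volume_mm3))
    if n == 0:
        return []
    idx = np.argwhere(region_mask)
    spacing = np.asarray(spec.grid.spacing)
    segments = []
    lo, hi = spec.vessel_length_mm
    for _ in range(n):
        center = (idx[rng.integers(len(idx))] + rng.random(3)) * spacing
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        half = 0.5 * rng.uniform(lo, hi)
        segments.append((center - half * u, center + half * u))
    return segments


def _rasterize_tubes(
    grid: VoxelGrid,
    segments: list[tuple[np.ndarray, np.ndarray]],
    radius_mm: float,
    clip_mask: np.ndarray,
) -> np.ndarray:
    coords = grid.coords_mm()
    spacing = np.asarray(grid.spacing)
    out = np.zeros(grid.shape, dtype=bool)
    for p0, p1 in segments:
        lo = np.minimum(p0, p1) - radius_mm
        hi = np.maximum(p0, p1) + radius_mm
        i0 = np.maximum(np.floor(lo / spacing - 0.5).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / spacing - 0.5).astype(int) + 1, grid.shape)
        if (i0 >= i1).any():
            continue
        sub = [coords[k][i0[k] : i1[k]] for k in range(3)]
        E, A, L = np.meshgrid(*sub, indexing="ij")
        pts = np.stack([E, A, L], axis=-1)
        u = p1 - p0
        L2 = float(u @ u)
        t = np.clip(((pts - p0) @ u) / max(L2, 1e-30), 0.0, 1.0)
        d2 = ((pts - (p0 + t[..., None] * u)) ** 2).sum(axis=-1)
        out[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] |= d2 <= radius_mm**2
    out &= clip_mask
    return out


def generate_phantom(
    spec: PhantomSpec,
    eps: ExtinctionTable | None = None,
    seed: int | None = None,
) -> tuple[PAVolumeSet, dict[float, FluenceMap], np.ndarray, PhantomTruth]:
    """Forward-simulate one dual-wavelength phantom acquisition.

    Returns ``(pa_volumes, fluence_maps, tumor_mask, truth)``. All
    randomness flows from one seeded generator (``seed`` overrides
    ``spec.seed``), with independent sub-streams per stage.
    """
    if eps is None:
        eps = load_extinction_table()
    grid = spec.grid
    seeds = np.random.SeedSequence(spec.seed if seed is None else seed).spawn(2)
    rng_geom = np.random.default_rng(seeds[0])
    rng_noise = np.random.default_rng(seeds[1])

    tumor = _ellipsoid_mask(grid, spec.tumor_center_mm, spec.tumor_semiaxes_mm)
    if not tumor.any():
        raise ValueError("tumor ellipsoid does not intersect the grid")
    masks = _region_masks(spec, tumor)

    c_hb = np.zeros(grid.shape)
    c_hbo2 = np.zeros(grid.shape)
    vessel_mask = np.zeros(grid.shape, dtype=bool)
    region_labels = np.full(grid.shape, -1, dtype=np.int8)
    names = tuple(r.name for r in spec.regions)
    vvf = {}
    for i, region in enumerate(spec.regions):
        rmask = masks[region.name]
        region_labels[rmask] = i
        segments = _sample_vessels(spec, region, rmask, rng_geom) if rmask.any() else []
        tubes = _rasterize_tubes(grid, segments, region.vessel_radius_mm, rmask)
        vessel_mask |= tubes
        vvf[region.name] = float(tubes.sum()) / max(int(rmask.sum()), 1)
        if vvf[region.name] > 0.5:
            import logging

            logging.getLogger(__name__).warning(
                "vessel volume fraction %.2f in region %s: tubes largely merged",
                vvf[region.name],
                region.name,
            )
        s = region.sto2_pct / 100.0
        amp = np.where(tubes, spec.hbt_amplitude, 0.0)
        amp = amp + np.where(
            rmask, region.diffuse_hbt_frac * spec.hbt_amplitude, 0.0
        )
        c_hbo2 += s * amp
        c_hb += (1.0 - s) * amp

    vascular_density = c_hb + c_hbo2
    if spec.psf_sigma_mm > 0:
        sigma_vox = [spec.psf_sigma_mm / s for s in grid.spacing]
        c_hb = ndimage.gaussian_filter(c_hb, sigma_vox)
        c_hbo2 = ndimage.gaussian_filter(c_hbo2, sigma_vox)

    hbt_true = c_hb + c_hbo2
    sto2_true = np.zeros(grid.shape)
    np.divide(c_hbo2, hbt_true, out=sto2_true, where=hbt_true > 0)
    sto2_true *= 100.0

    depth = grid.coords_mm()[1].reshape(1, -1, 1)
    fl = np.broadcast_to(
        np.exp(-spec.mu_eff_per_mm * depth), grid.shape
    ).copy()
    fluence = {
        wl: FluenceMap(grid=grid, wavelength=wl, volume=fl.copy())
        for wl in spec.wavelengths
    }

    volumes = {}
    for wl in spec.wavelengths:
        eps_hb, eps_hbo2 = eps.lookup(wl)
        p = fl * (eps_hb * c_hb + eps_hbo2 * c_hbo2)
        if spec.noise_sd > 0:
            p = p + rng_noise.normal(0.0, spec.noise_sd, size=grid.shape)
        volumes[wl] = np.clip(p, 0.0, None)

    truth = PhantomTruth(
        grid=grid,
        tumor_mask=tumor,
        vessel_mask=vessel_mask,
        region_labels=region_labels,
        region_names=names,
        sto2_pct=sto2_true,
        hbt=hbt_true,
        vascular_density=vascular_density,
        vessel_volume_fraction=vvf,
    )
    return PAVolumeSet(grid=grid, volumes=volumes), fluence, tumor, truth


def block_fractions(
    mask: np.ndarray,
    tumor: np.ndarray,
    grid: VoxelGrid,
    block_mm: float = 1.0,
    min_tumor_voxels: int = 1,
) -> tuple[list[tuple[int, int, int]], np.ndarray]:
    """Per-block fraction of ``mask`` voxels, tiling the tumor bounding box.

    Blocks are ``block_mm`` cubes in physical units; only blocks with at
    least ``min_tumor_voxels`` tumor voxels are reported. Fractions use
    the full block voxel count as denominator. Returns (block origins,
    fractions).
    """
    mask = np.asarray(mask, dtype=bool)
    tumor = np.asarray(tumor, dtype=bool)
    sizes = [max(int(round(block_mm / s)), 1) for s in grid.spacing]
    idx = np.argwhere(tumor)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    origins = []
    fracs = []
    for i in range(lo[0], hi[0], sizes[0]):
        for j in range(lo[1], hi[1], sizes[1]):
            for k in range(lo[2], hi[2], sizes[2]):
                box = (
                    slice(i, min(i + sizes[0], grid.shape[0])),
                    slice(j, min(j + sizes[1], grid.shape[1])),
                    slice(k, min(k + sizes[2], grid.shape[2])),
                )
                if tumor[box].sum() < min_tumor_voxels:
                    continue
                npx = sizes[0] * sizes[1] * sizes[2]
                origins.append((i, j, k))
                fracs.append(mask[box].sum() / npx)
    return origins, np.asarray(fracs)


def resample_slice(
    arr: np.ndarray,
    spacing_mm: tuple[float, float],
    pixel_mm: float,
    order: int = 0,
) -> np.ndarray:
    """Resample a 2D slice with anisotropic spacing onto isotropic pixels."""
    zoom = [s / pixel_mm for s in spacing_mm]
    return ndimage.zoom(np.asarray(arr, dtype=float), zoom, order=order)


def generate_pseudo_histology(
    truth: PhantomTruth,
    section_index: int,
    pixel_mm: float = 0.05,
    psf_sigma_mm: float = 0.1,
    noise_sd: float = 0.02,
    warp_amplitude_px: float = 0.0,
    warp_period_px: float = 48.0,
    seed: int = 0,
) -> tuple[IFImage, dict]:
    """Emulate a CD31/DAPI immunofluorescence section of the phantom.

    The CD31 channel is the vessel cross-section at ``section_index``,
    resampled to isotropic ``pixel_mm`` pixels, blurred by a Gaussian
    point-spread, and degraded with additive noise; DAPI is the tumor
    cross-section. A known smooth sinusoidal warp (row displacement
    ``A sin(2 pi c / period)``) can be applied to exercise registration.
    Returns the image and a dict with the warp field and the isotropically
    resampled section masks.
    """
    if not (0 <= section_index < truth.grid.shape[0]):
        raise IndexError(f"section {section_index} outside the volume")
    spacing2 = truth.grid.spacing[1:]
    tumor2 = resample_slice(truth.tumor_mask[section_index], spacing2, pixel_mm) > 0.5
    vessels2 = resample_slice(truth.vessel_mask[section_index], spacing2, pixel_mm) > 0.5
    if not tumor2.any():
        raise ValueError(f"section {section_index} contains no tumor")

    # Endothelial stain density tracks total vascular volume: resolvable
    # tubes plus the diffuse capillary background, not the tubes alone.
    if truth.vascular_density is not None:
        density2 = resample_slice(
            truth.vascular_density[section_index], spacing2, pixel_mm, order=1
        )
        scale = density2.max()
        density2 = density2 / scale if scale > 0 else density2
    else:
        density2 = vessels2.astype(float)

    rng = np.random.default_rng(seed)
    sigma_px = psf_sigma_mm / pixel_mm
    cd31 = ndimage.gaussian_filter(density2, sigma_px)
    dapi = ndimage.gaussian_filter(tumor2.astype(float), max(sigma_px / 2, 0.5))

    warp_rows = np.zeros(tumor2.shape)
    if warp_amplitude_px:
        cols = np.arange(tumor2.shape[1])
        warp_rows = np.broadcast_to(
            warp_amplitude_px * np.sin(2 * np.pi * cols / warp_period_px),
            tumor2.shape,
        ).copy()
        rr, cc = np.meshgrid(
            np.arange(tumor2.shape[0]), np.arange(tumor2.shape[1]), indexing="ij"
        )
        coords = np.stack([rr + warp_rows, cc])
        cd31 = ndimage.map_coordinates(cd31, coords, order=1)
        dapi = ndimage.map_coordinates(dapi, coords, order=1)

    if noise_sd > 0:
        cd31 = np.clip(cd31 + rng.normal(0, noise_sd, cd31.shape), 0, None)
        dapi = np.clip(dapi + rng.normal(0, noise_sd, dapi.shape), 0, None)

    image = IFImage(channels={"CD31": cd31, "DAPI": dapi}, pixel_size_mm=pixel_mm)
    info = {"tumor_iso": tumor2, "vessels_iso": vessels2, "warp_rows_px": warp_rows}
    return image, info


@dataclass(frozen=True)
class TreatmentEffect:
    """Per-timepoint regional parameter shifts for a longitudinal series.

    ``sto2_offsets_pp[t][region]`` shifts the region's StO2 (percentage
    points, clipped to [0, 100]); ``prune_fractions[t][region]`` removes
    that fraction of the region's vessel segments (a fixed seeded
    permutation makes pruning nested across timepoints).
    """

    timepoints: tuple[str, ...]
    sto2_offsets_pp: dict[str, dict[str, float]] = field(default_factory=dict)
    prune_fractions: dict[str, dict[str, float]] = field(default_factory=dict)


def default_sunitinib_effect(
    lvd_sto2_drop_pp: float = 12.0,
    hvd_sto2_recovery_pp: float = 20.0,
    lvd_prune_frac: float = 0.3,
) -> TreatmentEffect:
    """Anti-angiogenic response template: early deoxygenation and vessel
    pruning in the sparse (LVD-like) region, later reoxygenation of the
    dense (HVD-like) region."""
    return TreatmentEffect(
        timepoints=("D(-1)", "D(1)", "D(3)", "D(8)"),
        sto2_offsets_pp={
            "D(1)": {"sparse": -0.5 * lvd_sto2_drop_pp},
            "D(3)": {"sparse": -lvd_sto2_drop_pp},
            "D(8)": {"dense": hvd_sto2_recovery_pp},
        },
        prune_fractions={
            "D(3)": {"sparse": lvd_prune_frac},
            "D(8)": {"sparse": lvd_prune_frac},
        },
    )


def generate_longitudinal_series(
    spec: PhantomSpec,
    effect: TreatmentEffect,
    eps: ExtinctionTable | None = None,
    seed: int | None = None,
) -> list[dict]:
    """Simulate one subject over the effect's timepoints.

    The vessel geometry is drawn once (the same tumor imaged repeatedly);
    per timepoint, regional StO2 offsets and vessel pruning are applied
    before the forward model, and measurement noise is redrawn. Returns a
    list of ``{"timepoint", "pa", "fluence", "tumor", "truth"}`` records.
    """
    if eps is None:
        eps = load_extinction_table()
    base_seed = spec.seed if seed is None else seed
    seeds = np.random.SeedSequence(base_seed).spawn(2 + len(effect.timepoints))
    rng_geom = np.random.default_rng(seeds[0])
    rng_prune = np.random.default_rng(seeds[1])

    grid = spec.grid
    tumor = _ellipsoid_mask(grid, spec.tumor_center_mm, spec.tumor_semiaxes_mm)
    masks = _region_masks(spec, tumor)
    master_segments = {
        r.name: _sample_vessels(spec, r, masks[r.name], rng_geom)
        for r in spec.regions
    }
    prune_order = {
        name: rng_prune.permutation(len(segs))
        for name, segs in master_segments.items()
    }

    outputs = []
    for t_idx, tp in enumerate(effect.timepoints):
        offsets = effect.sto2_offsets_pp.get(tp, {})
        prunes = effect.prune_fractions.get(tp, {})
        rng_noise = np.random.default_rng(seeds[2 + t_idx])

        c_hb = np.zeros(grid.shape)
        c_hbo2 = np.zeros(grid.shape)
        vessel_mask = np.zeros(grid.shape, dtype=bool)
        region_labels = np.full(grid.shape, -1, dtype=np.int8)
        vvf = {}
        for i, region in enumerate(spec.regions):
            rmask = masks[region.name]
            region_labels[rmask] = i
            segs = master_segments[region.name]
            frac = prunes.get(region.name, 0.0)
            keep = len(segs) - int(np.ceil(frac * len(segs)))
            kept = [segs[j] for j in prune_order[region.name][:keep]]
            tubes = _rasterize_tubes(grid, kept, region.vessel_radius_mm, rmask)
            vessel_mask |= tubes
            vvf[region.name] = float(tubes.sum()) / max(int(rmask.sum()), 1)
            sto2 = float(np.clip(region.sto2_pct + offsets.get(region.name, 0.0), 0, 100))
            s = sto2 / 100.0
            amp = np.where(tubes, spec.hbt_amplitude, 0.0) + np.where(
                rmask, region.diffuse_hbt_frac * spec.hbt_amplitude, 0.0
            )
            c_hbo2 += s * amp
            c_hb += (1.0 - s) * amp

        vascular_density = c_hb + c_hbo2
        if spec.psf_sigma_mm > 0:
            sigma_vox = [spec.psf_sigma_mm / s for s in grid.spacing]
            c_hb = ndimage.gaussian_filter(c_hb, sigma_vox)
            c_hbo2 = ndimage.gaussian_filter(c_hbo2, sigma_vox)
        hbt_true = c_hb + c_hbo2
        sto2_true = np.zeros(grid.shape)
        np.divide(c_hbo2, hbt_true, out=sto2_true, where=hbt_true > 0)
        sto2_true *= 100.0

        depth = grid.coords_mm()[1].reshape(1, -1, 1)
        fl = np.broadcast_to(np.exp(-spec.mu_eff_per_mm * depth), grid.shape).copy()
        fluence = {
            wl: FluenceMap(grid=grid, wavelength=wl, volume=fl.copy())
            for wl in spec.wavelengths
        }
        volumes = {}
        for wl in spec.wavelengths:
            eps_hb, eps_hbo2 = eps.lookup(wl)
            p = fl * (eps_hb * c_hb + eps_hbo2 * c_hbo2)
            if spec.noise_sd > 0:
                p = p + rng_noise.normal(0.0, spec.noise_sd, size=grid.shape)
            volumes[wl] = np.clip(p, 0.0, None)

        outputs.append(
            {
                "timepoint": tp,
                "pa": PAVolumeSet(grid=grid, volumes=volumes),
                "fluence": fluence,
                "tumor": tumor,
                "truth": PhantomTruth(
                    grid=grid,
                    tumor_mask=tumor,
                    vessel_mask=vessel_mask,
                    region_labels=region_labels,
                    region_names=tuple(r.name for r in spec.regions),
                    sto2_pct=sto2_true,
                    hbt=hbt_true,
                    vascular_density=vascular_density,
                    vessel_volume_fraction=vvf,
                ),
            }
        )
    return outputs
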