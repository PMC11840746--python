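"""Phantom generator: reproducibility, forward-inverse consistency, and
end-to-end recovery of programmed regional structure."""

from dataclasses import replace

import numpy as np
import pytest

from vra.denoising import apply_noise_threshold, estimate_noise_threshold
from vra.histology import dice, grid_correlation, register_demons, tumor_mask_from_dapi, warp_image
from vra.phantom import (
    RegionSpec,
    block_fractions,
    default_sunitinib_effect,
    generate_longitudinal_series,
    generate_phantom,
    generate_pseudo_histology,
    resample_slice,
    two_region_spec,
    TreatmentEffect,
)
from vra.pipeline import run_longitudinal, run_vra
from vra.regional import delta_metrics, pearson_correlation
from vra.types import VoxelGrid
from vra.unmixing import compute_sto2, unmix_nnls


def test_bit_reproducible_under_fixed_seed(small_grid, eps_table):
    spec = two_region_spec(grid=small_grid, seed=11)
    pa1, _, _, t1 = generate_phantom(spec, eps=eps_table)
    pa2, _, _, t2 = generate_phantom(spec, eps=eps_table)
    for wl in pa1.wavelengths:
        assert np.array_equal(pa1.volumes[wl], pa2.volumes[wl])
    assert np.array_equal(t1.vessel_mask, t2.vessel_mask)


def test_different_seeds_differ(small_grid, eps_table):
    spec = two_region_spec(grid=small_grid, seed=11)
    pa1, _, _, _ = generate_phantom(spec, eps=eps_table, seed=1)
    pa2, _, _, _ = generate_phantom(spec, eps=eps_table, seed=2)
    assert not np.array_equal(pa1.volumes[750.0], pa2.volumes[750.0])


def test_noiseless_phantom_recovers_programmed_sto2(small_grid, eps_table):
    """Forward model then unmixing is the identity on clean inputs."""
    spec = replace(
        two_region_spec(grid=small_grid, seed=3),
        noise_sd=0.0,
        mu_eff_per_mm=0.0,
        psf_sigma_mm=0.0,
    )
    pa, _, tumor, truth = generate_phantom(spec, eps=eps_table)
    sto2 = compute_sto2(unmix_nnls(pa, eps_table))
    for region, want in (("dense", 70.0), ("sparse", 45.0)):
        vessels = truth.vessel_mask & truth.region_mask(region)
        assert vessels.any()
        np.testing.assert_allclose(sto2.values[vessels], want, atol=1e-6)


def test_noiseless_blurred_phantom_matches_truth_maps(small_grid, eps_table):
    """With the acoustic PSF on, the emitted per-voxel truth is still
    recovered exactly from a noiseless, fluence-free acquisition."""
    spec = replace(
        two_region_spec(grid=small_grid, seed=3), noise_sd=0.0, mu_eff_per_mm=0.0
    )
    pa, _, tumor, truth = generate_phantom(spec, eps=eps_table)
    maps = unmix_nnls(pa, eps_table)
    sto2 = compute_sto2(maps)
    signal = truth.hbt > 1e-12
    np.testing.assert_allclose(sto2.values[signal], truth.sto2_pct[signal], atol=1e-6)
    np.testing.assert_allclose(maps.c_hb + maps.c_hbo2, truth.hbt, atol=1e-12)


def test_avascular_phantom_is_mostly_noise_masked(small_grid, eps_table):
    """With no vessels and no capillary background the tumor is pure noise;
    the noise threshold sits at the center of the background distribution,
    so roughly half (not all) of the tumor is flagged avascular and no
    region carries genuine signal."""
    base = two_region_spec(grid=small_grid, seed=5)
    regions = tuple(
        replace(r, vessel_density=0.0, diffuse_hbt_frac=0.0) for r in base.regions
    )
    spec = replace(base, regions=regions)
    pa, fluence, tumor, truth = generate_phantom(spec, eps=eps_table)
    assert not truth.vessel_mask.any()
    res = run_vra(pa, tumor, eps_table, fluence=fluence)
    assert res.summary.av_fraction > 0.4


def test_block_fractions_counts(small_grid):
    tumor = np.zeros(small_grid.shape, bool)
    tumor[4:28, 8:40, 8:40] = True
    mask = np.zeros_like(tumor)
    mask[4:28, 8:40, 8:24] = True
    origins, fracs = block_fractions(mask, tumor, small_grid, block_mm=1.0)
    assert len(origins) == len(fracs)
    assert (fracs >= 0).all() and (fracs <= 1).all()
    assert fracs.max() > 0.9  # blocks fully inside the masked half


class TestPseudoHistology:
    def test_zero_warp_section_correlates_with_labels(self, small_phantom):
        spec = small_phantom["spec"]
        truth = small_phantom["truth"]
        res = small_phantom["result"]
        k = spec.grid.shape[0] // 2
        img, _ = generate_pseudo_histology(truth, k, noise_sd=0.0)
        labels_iso = resample_slice(
            res.labels.labels[k], spec.grid.spacing[1:], img.pixel_size_mm, order=0
        ).astype(int)
        gc = grid_correlation(img.channels["CD31"], labels_iso, img.pixel_size_mm)
        assert gc.r >= 0.7
        assert gc.n >= 10

    def test_known_warp_recovered_by_demons(self, small_phantom):
        spec = small_phantom["spec"]
        truth = small_phantom["truth"]
        k = spec.grid.shape[0] // 2
        img, info = generate_pseudo_histology(
            truth, k, noise_sd=0.01, warp_amplitude_px=5.0, seed=3
        )
        moving = tumor_mask_from_dapi(img.channels["DAPI"], threshold=0.3)
        fixed = info["tumor_iso"]
        f = register_demons(moving, fixed, pixel_size_mm=img.pixel_size_mm)
        warped = warp_image(moving.astype(float), f.field_px) > 0.5
        assert dice(warped, fixed) >= 0.9

    def test_avascular_section_is_noise_floor(self, small_grid, eps_table):
        base = two_region_spec(grid=small_grid, seed=9)
        regions = tuple(
            replace(r, vessel_density=0.0, diffuse_hbt_frac=0.0) for r in base.regions
        )
        spec = replace(base, regions=regions)
        _, _, _, truth = generate_phantom(spec, eps=eps_table)
        img, _ = generate_pseudo_histology(
            truth, small_grid.shape[0] // 2, noise_sd=0.02, seed=4
        )
        assert img.channels["CD31"].max() < 0.1  # nothing above the noise floor

    def test_out_of_volume_section_rejected(self, small_phantom):
        with pytest.raises(IndexError):
            generate_pseudo_histology(small_phantom["truth"], 10_000)


class TestLongitudinal:
    def test_null_effect_deltas_centered_at_zero(self, small_grid, eps_table):
        effect = TreatmentEffect(timepoints=("D(-1)", "D(3)"))
        deltas = []
        for seed in range(20):
            spec = two_region_spec(grid=small_grid, seed=seed)
            series = generate_longitudinal_series(spec, effect, eps=eps_table, seed=seed)
            results = run_longitudinal(series, eps_table)
            by_tp = {r.summary.timepoint: r.summary for r in results}
            deltas.append(
                delta_metrics(by_tp["D(-1)"], by_tp["D(3)"]).delta_sto2["LVD"]
            )
        deltas = np.asarray(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 2 * se + 0.5

    def test_programmed_effect_signs_and_ordering(self, small_grid, eps_table):
        effect = default_sunitinib_effect()
        for seed in range(10):
            spec = two_region_spec(grid=small_grid, seed=seed)
            series = generate_longitudinal_series(spec, effect, eps=eps_table, seed=seed)
            results = run_longitudinal(series, eps_table)
            by_tp = {r.summary.timepoint: r.summary for r in results}
            d3 = delta_metrics(by_tp["D(-1)"], by_tp["D(3)"])
            d8 = delta_metrics(by_tp["D(-1)"], by_tp["D(8)"])
            assert d3.delta_sto2["LVD"] < 0
            assert d8.delta_sto2["HVD"] > 0
            assert d8.delta_sto2["HVD"] > d8.delta_sto2["LVD"]

    def test_pruning_reduces_sparse_vessel_volume(self, small_grid, eps_table):
        effect = default_sunitinib_effect(lvd_prune_frac=0.5)
        spec = two_region_spec(grid=small_grid, seed=2)
        series = generate_longitudinal_series(spec, effect, eps=eps_table, seed=2)
        by_tp = {rec["timepoint"]: rec["truth"] for rec in series}
        before = by_tp["D(-1)"].vessel_volume_fraction["sparse"]
        after = by_tp["D(3)"].vessel_volume_fraction["sparse"]
        assert after < before
        assert by_tp["D(3)"].vessel_volume_fraction["dense"] == pytest.approx(
            by_tp["D(-1)"].vessel_volume_fraction["dense"]
        )
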