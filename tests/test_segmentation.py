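"""Frequency-domain filter and log-normal Otsu against brute-force oracles."""

import numpy as np
import pytest

from vra.segmentation import (
    OTSU_BINS,
    gaussian_highpass_3d,
    normalize_unit,
    nyquist_cutoff_radius,
    otsu_lognormal_threshold,
    segment_regions,
)
from vra.types import VoxelGrid


def dft_highpass_oracle(vol, grid, cutoff_fraction):
    """Direct DFT evaluation of the Gaussian high-pass, no FFT library.

    Builds explicit 1D DFT matrices W[k, x] = exp(-2 pi i k x / N) and the
    unshifted physical frequency axes from first principles.
    """
    vol = np.asarray(vol, float)
    mats = []
    freqs = []
    for n, d in zip(vol.shape, grid.spacing):
        k = np.arange(n)
        mats.append(np.exp(-2j * np.pi * np.outer(k, k) / n))
        f = np.where(k < (n + 1) // 2, k, k - n) / (n * d)
        freqs.append(f)
    F = np.einsum("ax,by,cz,xyz->abc", mats[0], mats[1], mats[2], vol.astype(complex))
    fe, fa, fl = np.meshgrid(*freqs, indexing="ij")
    D2 = fe**2 + fa**2 + fl**2
    d0 = cutoff_fraction * min(1.0 / (2 * s) for s in grid.spacing)
    H = 1.0 - np.exp(-D2 / (2 * d0**2))
    Fp = F * H
    inv = [m.conj() / n for m, n in zip(mats, vol.shape)]
    out = np.einsum("ax,by,cz,xyz->abc", inv[0], inv[1], inv[2], Fp)
    return out.real


def otsu_exhaustive_oracle(values, tie_rtol=1e-9):
    """Plain-loop search over all 255 cuts of the log histogram.

    Returns every threshold whose between-class variance is within
    floating-point tie tolerance of the maximum (adjacent cuts can tie
    exactly up to rounding order).
    """
    logv = np.log(np.asarray(values, float).ravel())
    counts, edges = np.histogram(logv, bins=OTSU_BINS)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    variances = np.full(OTSU_BINS - 1, -np.inf)
    for k in range(OTSU_BINS - 1):
        n0 = counts[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / n1
        variances[k] = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
    best = variances.max()
    ties = np.where(variances >= best - tie_rtol * abs(best))[0]
    return [float(np.exp(edges[k + 1])) for k in ties]


class TestNormalize:
    def test_basic_range(self):
        out = normalize_unit(np.array([[[0.0, 5.0, 10.0]]]))
        np.testing.assert_allclose(out, [[[0.0, 0.5, 1.0]]])

    def test_unit_range_identity(self, rng):
        vol = rng.random((4, 4, 4))
        vol.flat[0], vol.flat[-1] = 0.0, 1.0
        np.testing.assert_allclose(normalize_unit(vol), vol)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_unit(np.ones((4, 4, 4)))


class TestHighpassFilter:
    def test_constant_input_maps_to_zero(self):
        grid = VoxelGrid(shape=(8, 8, 8))
        out = gaussian_highpass_3d(np.full(grid.shape, 0.7), grid)
        assert np.abs(out).max() < 1e-10

    @pytest.mark.parametrize("shape", [(8, 8, 8), (8, 12, 16)])
    def test_matches_direct_dft_oracle(self, shape, rng):
        grid = VoxelGrid(shape=shape)
        vol = rng.random(shape)
        for cutoff in (0.02, 0.2):
            got = gaussian_highpass_3d(vol, grid, cutoff_fraction=cutoff)
            want = dft_highpass_oracle(vol, grid, cutoff)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_impulse_response_matches_oracle(self):
        grid = VoxelGrid(shape=(8, 8, 8))
        vol = np.zeros(grid.shape)
        vol[4, 4, 4] = 1.0
        got = gaussian_highpass_3d(vol, grid, cutoff_fraction=0.05)
        want = dft_highpass_oracle(vol, grid, 0.05)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_nyquist_checkerboard_passes_unchanged(self):
        """Pure highest-frequency content sits far above a small cutoff."""
        grid = VoxelGrid(shape=(8, 8, 8))
        i, j, k = np.indices(grid.shape)
        vol = 0.5 + 0.5 * ((-1.0) ** (i + j + k))
        out = gaussian_highpass_3d(vol, grid, cutoff_fraction=0.02)
        expected = vol - vol.mean()
        err = np.abs(out - expected).max() / np.abs(expected).max()
        assert err < 1e-3

    def test_dc_removed_on_random_input(self, rng):
        grid = VoxelGrid(shape=(8, 8, 8))
        out = gaussian_highpass_3d(rng.random(grid.shape) + 5.0, grid)
        assert abs(out.mean()) < 1e-8 * np.abs(out).max()

    def test_cutoff_radius_uses_physical_frequencies(self):
        grid = VoxelGrid(shape=(8, 8, 8), spacing=(0.15, 0.075, 0.165))
        # smallest Nyquist axis is lateral: 1/(2*0.165)
        assert nyquist_cutoff_radius(grid, 0.5) == pytest.approx(0.5 / (2 * 0.165))

    def test_too_small_volume_rejected(self):
        grid = VoxelGrid(shape=(2, 8, 8))
        with pytest.raises(ValueError, match="small"):
            gaussian_highpass_3d(np.zeros(grid.shape), grid)


class TestOtsuLogNormal:
    def test_two_point_separation(self):
        vals = np.array([0.2, 0.2, 3.0, 3.0])
        t = otsu_lognormal_threshold(vals)
        assert 0.2 < t <= 3.0

    def test_bimodal_lognormal_bracketing(self):
        rng = np.random.default_rng(42)
        lo = np.exp(rng.normal(np.log(0.01), 0.2, 10_000))
        hi = np.exp(rng.normal(np.log(1.0), 0.2, 10_000))
        t = otsu_lognormal_threshold(np.concatenate([lo, hi]))
        assert np.percentile(lo, 99) < t < np.percentile(hi, 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(50, 5000)
        modes = rng.integers(1, 4)
        vals = np.concatenate(
            [
                np.exp(rng.normal(rng.uniform(-4, 1), rng.uniform(0.1, 1.0), n))
                for _ in range(modes)
            ]
        )
        assert otsu_lognormal_threshold(vals) in otsu_exhaustive_oracle(vals)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            otsu_lognormal_threshold(np.array([0.0, 1.0, 2.0]))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_lognormal_threshold(np.array([1.0, 1.0]))


class TestSegmentRegions:
    GRID = VoxelGrid(shape=(8, 16, 16))

    def _tumor_av(self, rng, av_frac=0.2):
        tumor = np.zeros(self.GRID.shape, bool)
        tumor[:, 4:12, 4:12] = True
        av = tumor & (rng.random(self.GRID.shape) < av_frac)
        return tumor, av

    def test_partition_identity_random_fields(self, rng):
        for _ in range(5):
            filtered = rng.normal(size=self.GRID.shape)
            tumor, av = self._tumor_av(rng)
            labels, _ = segment_regions(filtered, tumor, av, self.GRID)
            n = labels.hvd.sum() + labels.lvd.sum() + labels.av.sum()
            assert n == tumor.sum()
            assert not (labels.hvd & labels.lvd).any()

    def test_all_negative_filtered_gives_no_hvd(self, rng):
        tumor, av = self._tumor_av(rng)
        filtered = -np.abs(rng.normal(size=self.GRID.shape)) - 0.1
        labels, _ = segment_regions(filtered, tumor, av, self.GRID)
        assert not labels.hvd.any()
        assert labels.lvd.sum() == tumor.sum() - av.sum()

    def test_high_filtered_value_beats_av_label(self, rng):
        """A voxel above the Otsu threshold is HVD even if noise-masked."""
        tumor, av = self._tumor_av(rng)
        filtered = rng.normal(size=self.GRID.shape) * 0.01
        target = tuple(np.argwhere(av)[0])
        filtered[target] = 100.0
        labels, t = segment_regions(filtered, tumor, av, self.GRID)
        assert labels.labels[target] == 3

    def test_deterministic_labels(self, rng):
        filtered = rng.normal(size=self.GRID.shape)
        tumor, av = self._tumor_av(rng)
        l1, t1 = segment_regions(filtered, tumor, av, self.GRID)
        l2, t2 = segment_regions(filtered.copy(), tumor.copy(), av.copy(), self.GRID)
        assert t1 == t2
        assert np.array_equal(l1.labels, l2.labels)

    def test_empty_tumor_rejected(self):
        empty = np.zeros(self.GRID.shape, bool)
        with pytest.raises(ValueError, match="empty"):
            segment_regions(np.zeros(self.GRID.shape), empty, empty, self.GRID)
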