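# Methods

## Signal model and unmixing

The photoacoustic pressure amplitude at wavelength λ and depth z is
modeled as P(λ, z) ∝ Γ η_th F(λ, z) μ_a(λ, z), with Γ the Grüneisen
parameter, η_th the heat-conversion fraction, F the optical fluence, and
μ_a the absorption coefficient. In the NIR-I window, and for subjects
without skin pigmentation, hemoglobin dominates absorption, so
μ_a = ε_Hb(λ) C_Hb + ε_HbO₂(λ) C_HbO₂. Γ and η_th are treated as
constants and absorbed into the arbitrary unit scale: concentrations,
HbT, and every downstream metric are ratios or differences, so the
absolute scale never enters a result.

Fluence maps are consumed as inputs (the package does not run photon
transport); compensation divides voxelwise, with a relative floor
(default 10⁻⁶ × map maximum) below which a voxel is marked invalid
rather than divided — invalidity propagates through every later
statistic.

Per-voxel unmixing solves the 2×2 non-negative least-squares problem in
closed form: take the unconstrained solve; if a component is negative,
clamp each component to zero in turn, solve the remaining one-variable
problem, and keep the lower-residual corner. For two wavelengths this is
exact (verified in the tests against a multi-scale grid-search minimizer
and an iterative NNLS solver) and runs vectorized over whole volumes.
Tiny negative intensities (> −10⁻⁹ × volume maximum), which arise from
beamforming and filtering artifacts, are clipped to zero with a logged
count; larger negatives abort the run.

### Extinction table

The packaged table (`src/vra/data/hb_extinction.csv`) covers 680–970 nm
at 10 nm steps, compiled from the standard tabulated hemoglobin molar
extinction spectra; users can override it with any CSV carrying
`wavelength_nm, eps_Hb, eps_HbO2`. Pinning a table in the package, rather
than pointing at the literature, is what makes StO₂ values reproducible
across installations. At the default 750/850 nm pair the system matrix is
well conditioned (deoxyhemoglobin dominant at 750 nm, oxyhemoglobin at
850 nm).

## Noise floor and avascular exclusion

The HbT noise threshold is learned from two background rectangles per
frame (default 50×50 pixels in the shallow corners, configurable): mean
over the two ROIs per frame, mean over frames per volume, maximum over a
subject's volumes, mean over subjects, rounded half-even to four decimal
places on the a.u. scale. Tumor voxels with HbT strictly below the
threshold are avascular; their StO₂ is set to zero and excluded from all
means. Rounding to 10⁻⁴ is meaningful because the a.u. scale of the
pipeline puts tissue HbT at ~10⁻³ and the noise floor at a few 10⁻⁴.

## Regional segmentation

The normalized HbT volume I ∈ [0, 1] (min–max over the full volume,
before masking) is high-pass filtered in the 3D Fourier domain:

    I′ = ℱ⁻¹[ (1 − exp(−D²/2D₀²)) · ℱ[I] ]

- **Frequency radius in physical units.** D is measured in cycles/mm
  using each axis's voxel spacing. The scan grid is strongly anisotropic
  (0.150/0.075/0.165 mm); an index-space radius would make the filter
  direction-dependent in physical space.
- **Cutoff D₀.** Parameterized as `cutoff_fraction` × the smallest axis
  Nyquist frequency, recorded in the provenance output of every run.
  The default, 0.02 (D₀ ≈ 0.061 cycles/mm, equivalent to subtracting a
  local mean of Gaussian width σ ≈ 2.6 mm), was calibrated once on the
  two-region phantom: it is the largest value at which the HVD label
  recovers the programmed dense region at Dice ≥ 0.75, with performance
  flat below it and degrading above it (Dice 0.65 at 0.05, 0.55 at 0.1).
  Intuitively, structure coarser than ~2.5 mm — bulk tumor background
  and depth trends — is suppressed, while millimetric vascular texture
  passes.
- **Edge handling.** Plain periodic FFT, no padding or windowing. Wrap-
  around artifacts at the volume boundary are a known limitation; the
  tumor mask keeps them out of the statistics in typical scans where the
  tumor does not touch the volume edge.
- The imaginary residue of the inverse transform is asserted below 10⁻⁸
  (relative) and discarded; the DC term is removed exactly. I′ is used
  only to assign labels — never in any quantitative statistic.

Inside the tumor, only positive I′ values are candidates for HVD: the
high-pass response oscillates around zero and its dark lobes are not
vessels, while the log-normal threshold needs positive support. The Otsu
threshold maximizes between-class variance on a 256-bin histogram of
log I′ (filtered HbT intensities are approximately log-normal) and is
mapped back to the intensity scale as the upper edge of the maximizing
bin, so that `I′ ≥ t*` reproduces the histogram classes exactly; an
exhaustive search over all 255 cuts is the test oracle. HVD = tumor
voxels with I′ ≥ t*; AV comes from the noise threshold (a voxel that
clears t* is HVD even if noise-masked); LVD is the remainder. The
partition identity |HVD| + |LVD| + |AV| = |tumor| is asserted inside the
pipeline on every run, not only in tests.

## Regional statistics

StO₂ means are over valid voxels only (AV and fluence-invalid voxels are
omitted); the whole-tumor HbT mean includes every tumor voxel, because
avascularity is itself defined from HbT and excluding sub-threshold
voxels would bias the blood-content estimate upward. Regional means pool
voxels across frames (equivalent to frame-weighting for uniform
spacing). Deltas are later − earlier; StO₂ deltas are reported in
percentage points. Pearson r with a two-tailed t-distribution p (n − 2
df) is provided for the validation analyses; group-level hypothesis
testing is out of scope.

## Histology validation arm

IF channels are min–max normalized and binarized at a per-channel
threshold (default 0.1 of the normalized range — autofluorescence levels
are instrument-specific and must be recorded, so they are explicit
config values rather than manual choices). The tumor mask comes from
DAPI: binarize, fill holes, keep the largest 8-connected component.
Registration onto the imaging frame composes a center-of-mass
translation (coarse alignment) with a coarse-to-fine diffeomorphic
demons refinement (3 pyramid levels, 50 iterations/level, Gaussian
update smoothing σ = 2 px; SimpleITK backend). The returned field is the
best of {identity, translation, composed} by mask Dice, so registration
can never reduce overlap — asserted per call. The 1 mm-grid correlation
tiles the tumor bounding box with non-overlapping square ROIs anchored
at the box origin; ROIs with any tumor pixel are kept, and both the mean
CD31 intensity and the HVD fraction use the full ROI pixel count as
denominator. Positivity ratios (Ki-67⁺/DAPI⁺, αSMA⁺/CD31⁺, TL⁺/CD31⁺)
are pixel-count ratios inside the tumor mask and may exceed 1 when the
numerator stain is not nested in the denominator stain.

## Phantom design

The simulator emulates the data regime the segmentation assumes, not
acoustically realistic PA physics:

- **Geometry.** Ellipsoidal tumor (~180 mm³ on the default 64×96×96
  grid) split into sub-regions; vessels are straight tube segments
  (Poisson count at the stated density per mm³, length 0.8–1.6 mm),
  clipped to their region. Branching trees would add parameters without
  adding test power.
- **Regions.** Default two-region phantom: dense half 5 vessels/mm³,
  radius 0.12 mm, 70% StO₂; sparse half 0.5 vessels/mm³, radius
  0.08 mm, 45% StO₂ — vessel densities and the treatment-effect
  magnitudes below are the study conditions the pipeline is specified
  against.
- **Diffuse background.** Every tumor voxel carries a sub-resolution
  capillary HbT at 15% of the intravascular amplitude (5×10⁻³ a.u.), at
  the region's StO₂. Without it, LVD regions would be pure noise, which
  neither matches perfused tissue nor supports regional StO₂ estimates.
- **Acoustic blur.** Concentration maps are blurred with an isotropic
  Gaussian PSF (σ = 0.25 mm), merging the dense region into a
  near-continuum of signal while sparse-region vessels stay isolated dim
  bumps — the contrast the frequency-domain segmentation exploits. The
  emitted per-voxel truth (StO₂, HbT) is taken after the blur, so
  noiseless forward–inverse consistency is exact by construction.
- **Fluence and noise.** 1D exponential depth decay (μ_eff = 0.3 mm⁻¹)
  per wavelength; additive Gaussian noise (σ = 0.1 a.u., i.e. SNR ≈ 35
  on vessels and ≈ 5 on diffuse tissue after frame averaging), clipped
  at zero as detected amplitudes are non-negative. The resulting pooled
  noise threshold (~3×10⁻⁴ a.u.) keeps the round-to-10⁻⁴ rule
  meaningful.
- **Longitudinal series.** One vessel network per subject; per
  timepoint, regional StO₂ offsets and nested random pruning of a
  region's segments are applied before the forward model, and noise is
  redrawn. The default effect template mirrors an anti-angiogenic
  response: sparse-region StO₂ −6 pp at D(1) and −12 pp at D(3) with 30%
  vessel pruning, dense-region +20 pp at D(8).
- **Seeding.** One seed per run, split into independent sub-streams
  (geometry, pruning, per-timepoint noise); outputs are bit-reproducible
  under a fixed seed.

What passing phantom tests do **not** show: robustness to speckle,
bandlimited detection, heterogeneous fluence in 3D, motion, segmentation
of non-ellipsoidal or infiltrative tumors, or real staining variability.
The phantom validates the machinery and its statistical behavior, not
in-vivo performance.

## Problem sizes and numerical choices

The full-size recovery analyses use the 64×96×96 default grid; the
longitudinal simulations (100 subjects × 4 timepoints in the acceptance
script) use a 32×48×48 grid — chosen so each simulated subject carries a
few dozen to a few hundred vessels, enough for stable regional means
while keeping a complete replicate study a desk-scale computation.
Degenerate inputs fail loudly rather than silently: constant HbT volumes
(normalization undefined), empty tumor masks, all-zero IF channels,
singular extinction pairs, and sub-4-voxel axes are errors; an
all-avascular tumor is a warning (HVD and LVD legitimately empty).
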