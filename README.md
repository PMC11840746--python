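# vra — vascular regional analysis for macroscopic photoacoustic imaging

Macroscopic ultrasound-guided photoacoustic imaging (US-PAI) reaches
centimeter depths but cannot resolve individual microvessels, so classical
microvessel-density counting is impossible. `vra` implements a
frequency-domain surrogate: it partitions a tumor into regions of **high
vascular density (HVD)**, **low vascular density (LVD)**, and **avascular
(AV)** voxels directly from volumetric hemoglobin maps, then tracks
regional oxygenation and blood content over a treatment course. It is
aimed at preclinical imaging groups monitoring anti-angiogenic therapy
(e.g. receptor tyrosine kinase inhibitors) in tumor xenografts.

## Method

Starting from dual-wavelength (750/850 nm) PA intensity volumes
P(λ) and per-wavelength fluence maps F(λ):

1. **Spectral unmixing.** After fluence compensation
   P′ = P/F, each voxel is unmixed by non-negative least squares,

       (C_Hb, C_HbO₂) = argmin_{c ≥ 0} ‖ E c − P′ ‖₂ ,

   where E is the 2×2 matrix of molar extinction coefficients
   ε_Hb(λ), ε_HbO₂(λ). From these, StO₂ = C_HbO₂ / (C_Hb + C_HbO₂)
   and HbT = C_Hb + C_HbO₂ (arbitrary units; the Grüneisen parameter and
   heat-conversion fraction are constants absorbed into the scale).
2. **Denoising.** An HbT noise floor is estimated from two background
   ROIs per frame (frame mean → volume mean → per-subject maximum →
   pooled mean, rounded to 4 decimals). Tumor voxels below it are AV:
   their StO₂ is zeroed and excluded from all statistics.
3. **Regional segmentation.** The HbT volume is normalized to [0, 1],
   transformed with a 3D FFT, and multiplied by a Gaussian high-pass
   H(u,v,w) = 1 − exp(−D²/2D₀²), with the frequency radius D in
   physical units (cycles/mm) so anisotropic voxels are handled
   correctly. The filtered volume I′ is binarized inside the tumor with
   an Otsu threshold computed on log-intensities (filtered HbT is
   approximately log-normal): voxels at or above the threshold are HVD,
   the remainder minus AV is LVD. By construction
   |HVD| + |LVD| + |AV| = |tumor| on every run.
4. **Regional metrics.** Per-region mean StO₂ / HbT, region fractions,
   and longitudinal deltas ΔStO₂ (percentage points) and ΔHbT between
   named timepoints (e.g. D(−1) pre-treatment vs D(3)).
5. **Histology validation.** CD31/DAPI immunofluorescence support:
   channel binarization, DAPI tumor masking, demons registration of the
   section onto the imaging frame, 1 mm-grid correlation of mean CD31
   intensity with HVD pixel fraction, and the Ki-67 / vascular
   normalization (αSMA⁺/CD31⁺) / perfusion (TL⁺/CD31⁺) indices.

A vessel-network phantom (`vra.phantom`) with known regional density,
oxygenation, and treatment-effect schedules makes the whole chain testable
without acquired data.

## Worked example

Simulate the default two-region phantom (an ellipsoidal ~180 mm³ tumor
whose lateral halves hold 5 and 0.5 vessels/mm³ at 70% and 45% StO₂) and
run the full pipeline:

```python
import vra
from vra.phantom import two_region_spec, generate_phantom, block_fractions
from vra.histology import dice
from vra.regional import pearson_correlation

eps = vra.load_extinction_table()
spec = two_region_spec(seed=1)
pa, fluence, tumor, truth = generate_phantom(spec, eps=eps, seed=1)
res = vra.run_vra(pa, tumor, eps, fluence=fluence)

s = res.summary
print(res.noise_threshold, res.otsu_threshold)
print(s.hvd_fraction, s.lvd_fraction, s.av_fraction)
print(s.regions["HVD"].mean_sto2, s.regions["LVD"].mean_sto2)
print(dice(res.labels.hvd, truth.region_mask("dense")))
```

prints (formatted):

```
noise threshold (a.u.): 0.0003
Otsu threshold on I': 0.1079
fractions  HVD 0.596  LVD 0.381  AV 0.023
HVD   mean StO2  66.2 %   mean HbT 1.71e-03 a.u.   (57946 voxels)
LVD   mean StO2  43.5 %   mean HbT 6.73e-04 a.u.   (36989 voxels)
tumor mean StO2  57.3 %   mean HbT 1.28e-03 a.u.   (97160 voxels)
Dice(HVD, dense half) = 0.810
1 mm block vessel fraction vs HVD fraction: r = 0.904 (p = 7.9e-110, n = 295)
```

The HVD label recovers the densely vascularized half (Dice 0.81), the
regional StO₂ means sit close to the programmed 70% / 45% (pulled toward
each other by boundary mixing and measurement noise), and per-1 mm-block
HVD fraction tracks true vessel volume fraction (r = 0.90) — the
phantom analogue of correlating HVD fraction against CD31 staining.

The same steps are available from the shell:

```sh
vra simulate --seed 1 --out phantom/
vra unmix --pa750 phantom/PA_750nm.tif --pa850 phantom/PA_850nm.tif \
    --fluence750 phantom/fluence_750nm.tif --fluence850 phantom/fluence_850nm.tif \
    --out maps/
vra segment --hbt maps/HbT.tif --sto2 maps/StO2.tif \
    --tumor-mask phantom/tumor_mask.tif --out seg/
vra summarize --labels seg/region_labels.tif --sto2 seg/StO2_denoised.tif \
    --hbt maps/HbT.tif --subject m1 --timepoint "D(-1)" --out summary.csv
```

## Layout

- `src/vra/types.py`, `src/vra/io.py` — containers, TIFF/NIfTI + JSON
  sidecar I/O, packaged hemoglobin extinction table (680–970 nm,
  CSV-overridable)
- `src/vra/unmixing.py` — fluence compensation, closed-form 2×2 NNLS,
  StO₂/HbT maps
- `src/vra/denoising.py` — HbT noise floor and AV mask
- `src/vra/segmentation.py` — Gaussian high-pass, log-normal Otsu,
  HVD/LVD/AV partition
- `src/vra/regional.py` — regional summaries, deltas, Pearson statistics
- `src/vra/histology.py` — IF preprocessing, demons registration,
  CD31↔HVD grid correlation, positivity indices
- `src/vra/phantom.py` — vessel-network simulator and longitudinal
  treatment-effect series
- `docs/methods.md` — model assumptions, parameter choices, and
  limitations
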