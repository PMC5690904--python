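# Methods

This document records the model, algorithms, parameter choices, and known
limitations of `sctforge`. Units are millimetres (mm), degrees (deg), Hounsfield
units (HU), and gray (Gy) throughout.

## 1. Problem statement

In an MR-only radiotherapy workflow for the male pelvis, no planning CT is
acquired, yet two tasks need CT-like electron-density information:

1. **Dose calculation** for intensity-modulated plans, and
2. **Patient localization**: rigid registration of daily cone-beam CT (CBCT)
   against a CT-valued reference.

`sctforge` synthesizes a substitute CT (S-CT) from the subject's MR image and a
library of co-registered MR–CT atlas pairs, then quantifies how well the S-CT
stands in for the true CT on both tasks. Because real patient data cannot ship
with a software package, the package includes a digital pelvis phantom that
generates arbitrarily many anatomically consistent MR/CT/label triples, so the
whole pipeline is testable end to end against exact ground truth.

## 2. Digital pelvis phantom (`sctforge.phantom`)

### 2.1 Geometry model

Each subject is built from one analytic label function evaluated on a regular
grid. The template anatomy consists of:

| structure | shape | default size |
|---|---|---|
| body | ellipsoid | semi-axes (110, 85, 92) mm |
| sacrum | ellipsoid at (0, 55, 0) | semi-axes (30, 14, 60) mm |
| femoral heads | cylinders at x = ±65 | radius 16 mm, half-length 70 mm |
| bladder | ellipsoid at (0, −25, 25) | semi-axes (26, 22, 20) mm |
| prostate | ellipsoid at (0, −5, −15) | semi-axes (18, 16, 15) mm |
| rectum | tube at y = 25 | outer 15 mm, lumen 8 mm, z ∈ [−60, 50] |
| rectal air | lumen segment | z ∈ [−10, 30] |

Labels are assigned by priority (body → bone → rectum → air → bladder →
prostate) so overlapping shapes resolve deterministically. Per-subject
variation is (a) random jitter of organ centers (±6 mm) and radii (±12 %,
bladder ±25 %), and (b) a smooth random displacement field (default amplitude
8 mm, Gaussian smoothing 30 mm) applied to the *coordinates* at which the label
function is evaluated. Because MR, CT and labels all derive from the same
warped label function, the three are anatomically consistent by construction —
there is no inter-modality registration error inside a subject.

### 2.2 Intensity model

Tissue classes map to mean HU / MR values with additive Gaussian noise plus a
smooth texture field evaluated in material (pre-warp) coordinates, so texture
deforms with the anatomy and gives deformable registration usable signal inside
otherwise uniform regions. The MR intensity mapping is deliberately
**non-monotone** in HU (bone is dark on MR, bladder is bright), so no global
intensity transform can convert MR to CT — the core difficulty the atlas method
addresses. Air is exactly −1000 HU before noise. Two cohort members (indices 3
and 7) receive +300 HU bladder contrast, emulating patients whose bladder
content departs from the library average; these are the subjects a naive
atlas-average handles worst.

### 2.3 Realism limits

The phantom is smooth-organ, piecewise-near-constant anatomy: no trabecular
bone gradients, no fat/muscle interdigitation, no MR bias field, no CT beam
hardening. Absolute error magnitudes are therefore optimistic relative to
clinical data; *relative* comparisons between methods (selection vs direct
mean, atlas-count sweeps) are the meaningful outputs.

## 3. Registration (`sctforge.registration`)

- **Conventions.** Grids are axis-aligned; world = origin + index · spacing.
  Displacement fields (DVFs) are *pull/backward*: `out(p) = moving(p + d(p))`
  with `d` in mm on the fixed grid. Rigid transforms act as
  `p' = R (p − c) + c + t` with fixed-axis XYZ rotation `R = Rz·Ry·Rx`,
  resampling again by pull-back.
- **Deformable MR–MR**: multiscale (shrink 4/2/1) SimpleITK fast symmetric
  forces Demons, update-field smoothing 4 mm. Used for atlas-to-subject
  propagation since both images are the same modality.
- **Deformable MR–CT**: Mattes mutual-information B-spline registration, used
  when an atlas pair needs intra-pair alignment (the phantom generates
  voxel-matched pairs, so the default pairing DVF is zero).
- **Rigid CT/CBCT**: SimpleITK Euler3D with correlation metric, a fixed-image
  mask ("clipbox", bony anatomy dilated by 2 voxels), and three fixed
  multistart offsets. The recovered transform is re-expressed in the phantom's
  truth convention (inverse of the ITK fixed→moving map, recentered at the
  volume center), so recovered and simulated offsets are directly comparable.

## 4. Atlas library and segmentation (`sctforge.atlaslib`, `sctforge.segmentation`)

Each atlas entry stores the MR, the CT deformed into MR space, and ROI masks.
For a new subject, every atlas MR is registered to the subject MR and the DVF
is applied to the atlas CT (linear) and masks (nearest neighbour). Labels are
fused with **intensity-weighted voting**: per atlas, per voxel, weight
`1 / (ε + local mean |subject MR − deformed atlas MR|)` over a 3-voxel patch;
a voxel joins the fused mask when the weighted vote fraction is ≥ 0.5. Air and
the body contour are obtained by MR thresholding (percentile-derived
thresholds) rather than fusion, since both have strong intensity signatures.
Overlap is scored with the Dice coefficient (1.0 for two empty masks).

## 5. Synthetic-CT synthesis (`sctforge.sct`)

For subject voxel `p`, atlas `i` is *selected* when its deformed masks agree
with the subject's masks for every ROI in the selection set:

```
w_i(p) = Π_j [ subject_mask_j(p) == deformed_atlas_mask_{i,j}(p) ]
```

The S-CT value is the mean of the selected atlas CT values; where no atlas is
selected the mean over *all* atlases is used (fallback); finally every voxel of
the subject's air mask is overridden to −1000 HU. The default selection set is
all six ROIs (air, bone, bladder, prostate, rectum, skin). Voxels that some
deformed atlas cannot see (outside the moving image domain) are excluded via
per-atlas validity masks. The **direct-mean baseline** skips selection entirely
(mean over all valid atlases + air override). Diagnostics record the per-voxel
selected count, fallback fraction, and per-atlas selection rates.

## 6. Evaluation (`sctforge.evaluation`)

- **HU error**: signed mean ± SD per ROI, plus cumulative |error| histogram and
  quantiles over soft tissue (body minus bone, bladder, prostate, rectum, air).
- **Dose proxy**: per beam, the CT volume is rotated to the gantry angle
  (`scipy.ndimage.rotate`), attenuation `μ = μ_water (1 + HU/1000)` (clipped at
  0) is accumulated along the beam axis (`cumsum · Δy`), and dose decays as
  `exp(−∫μ)` inside the beam aperture, which is the projection of the rotated
  PTV-derived field mask. Seven equispaced beams; the summed dose is normalized
  so the PTV mean equals the prescription (79.2 Gy). This is a transmission
  model, not a dose engine: no scatter, no buildup, no energy spectrum. It is
  sufficient to expose HU errors as dose errors along every ray.
- **2D local gamma**: for each evaluated pixel, the minimum over a disc of
  radius 3 × distance-criterion (step ≈ distance/10) of
  `sqrt(Δdose²/(δ·D_ref(r))² + r²/Δd²)` with **local** normalization by the
  interpolated reference dose at the search point. Pixels below 10 % of the
  reference maximum are excluded from pass rates. Verified against an
  exhaustive fine-grid brute-force oracle.
- **DVH**: `Dx = quantile(ROI doses, 1 − x/100)` with linear interpolation
  (NumPy `method="linear"`), i.e. for doses 1..100 Gy, D99 = 1.99 Gy and
  D50 = 50.5 Gy. Discrepancies are reported relative to the prescription.
- **Localization**: simulated CBCTs (true CT + known rigid offset + noise) are
  rigidly registered to both the S-CT and the true CT; the comparison is the
  translation-vector norm difference and per-axis rotation differences between
  the two recovered transforms.
- **Leave-one-out orchestration**: for each of N subjects, the other N−1 form
  the library; registrations are computed once and reused for the atlas-count
  sweep (fusing prefixes of the propagated list). Per-subject failures are
  recorded and do not abort the run. Per-subject randomness derives from
  `default_rng([seed, subject_index])`, so results are reproducible and
  independent of evaluation order.

## 7. Problem sizes and numerical choices

Default grids are 64×64×48 at 4 mm spacing (package choice balancing anatomical
legibility against suite size; the physics and algorithms are
resolution-independent and all sizes are configurable). Cohorts default to 10
subjects with 9-atlas leave-one-out libraries. Gamma is evaluated on 3 axial
slices per ROI, chosen around each ROI's centroid within the dosed z-range.
All stochastic components take explicit integer seeds (< 2³¹) through
`numpy.random.default_rng`; no global random state is used.

## 8. Known limitations

- The dose proxy ignores scatter and buildup; absolute gamma pass rates are not
  comparable to clinical QA numbers.
- The phantom's tissue uniformity makes segmentation easier than clinical MR;
  Dice values are upper bounds.
- Rigid CBCT localization assumes the anatomy itself is rigid between CT and
  CBCT (only pose and noise differ), so it measures the reference-image effect
  in isolation.
- Gamma is 2D per-slice, not 3D.
- The B-spline MR–CT registration path is exercised lightly (the phantom
  produces intrinsically aligned pairs); on real data it would carry more of
  the error budget.
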