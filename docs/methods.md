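# Methods

`cbctrad` is a synthetic test bench for preclinical cone-beam CT (CBCT)
radiomics. It answers a workflow question, not a biology question: *which of
the hundreds of radiomics features extracted from small-animal CBCT scans are
stable enough — across imaging energy, intensity discretisation, slice
thickness and segmentation volume — to be used as candidate imaging
biomarkers?* Everything needed to study that question is generated in
silico, so the whole pipeline is reproducible from a seed.

## Digital phantoms and scan emulation

**Mouse phantom.** A tissue-equivalent mouse phantom is emulated as an
ellipsoid soft-tissue body, two ellipsoid lungs and a cylindrical spine, with
compartment densities 1.01 (soft tissue), 0.68 (lung) and 1.39 g/cm³ (bone).
Intensities follow an affine density→intensity calibration,
`I = 16677.2 · ρ` scanner units, anchored so soft tissue sits at 16,844
units — the scale a small-animal irradiator's onboard CBCT reports for soft
tissue. No X-ray physics is modelled; the calibration only places synthetic
values on a realistic scale, and compartment mean intensities are monotone in
density by construction. Anatomical realism is a non-goal: the geometry
exists to give ROI placement meaningful compartments (the caudal half of the
body is kept free of lung and bone so spherical ROIs sample homogeneous soft
tissue).

**Texture phantom.** A 60 mm plastic block with four full-length cylindrical
inserts (20 mm diameter): air, solid water, PVC and acetal. Insert mean
intensities use measured on-scanner values (1861, 2940, 4138 and 2917 units)
rather than the density calibration, because scanner response — not density —
sets that scale (acetal is denser than PVC yet darker). The default grid
samples the block at 0.5 mm isotropic (120³ voxels), a deliberate
resolution/compute trade-off; ROI statistics at the 42 mm³ segmentation are
insensitive to it.

**Texture and noise model.** Each material carries a frozen Gaussian texture
field with configurable sd (default 250 units for mouse compartments) and
spatial correlation length (default 0.4 mm), built by smoothing white noise
and renormalising to unit variance (periodic smoothing keeps the variance
stationary; sample sd converges to the configured sd at large voxel counts).
The texture field is part of the phantom: it is identical in scan and rescan.
Acquisition adds white Gaussian noise per scan, a deterministic slowly
varying bias field per protocol, and a global contrast scale:

    scan = contrast_scale · phantom + bias(energy) + N(0, noise_sd²).

Energy (40/50/60 kV) is emulated *only* through these parameters —
noise_sd 350/250/180, bias amplitude 250/180/120, contrast 0.94/0.97/1.00 —
reflecting that lower-energy CBCT is noisier and more artefact-prone. The
bias field is a fixed function of the energy label, so it cancels within a
scan–rescan pair (repeatability is noise-limited) but differs across
energies (reproducibility across energies is systematically limited, the
qualitatively expected behaviour). Because the pair differs only in noise,
the voxelwise sd of (scan − rescan)/√2 recovers noise_sd exactly, which the
tests check at 2% over ≥10⁵ voxels.

**Tumour cohorts.** Two arms of n = 9 subjects, each a soft-tissue body with
one spherical tumour of 94.25 mm³ (the standard tumour segmentation volume).
The second arm's texture mean is shifted by `effect_size` × texture sd
(default 1.5); effect 0 gives an exact null for calibrating the false-positive
rate of the downstream paired t-tests. Each subject has an independent
texture realisation and a jittered tumour centre.

## Preprocessing

* **I/O** — NIfTI and NRRD via SimpleITK; spacing is always honoured from
  headers, masks stored as uint8. Axis 0 is the slice direction.
* **Slice-thickness resampling** — only the slice-axis spacing changes
  (in-plane spacing is untouched); the image is interpolated linearly, masks
  nearest-neighbour, and the new slice count is `round(extent/thickness)` so
  the physical extent is preserved within one voxel. Masks are resampled
  alongside images in the thickness sweep.
* **Discretisation** — fixed bin width anchored at the ROI minimum:
  `level(x) = floor((x − min)/w) + 1`, with Ng the level of the maximum. The
  rule is translation-covariant: adding a constant to all intensities leaves
  levels unchanged. Default width 25; the sweep covers 10/25/50/100.
* **Spherical segmentation** — a voxel is inside iff its centre lies within
  `r = (3V/4π)^{1/3}` of the centre. At 0.26 mm spacing the achieved volume
  is within 5% of the request for all standard volumes
  (27.68–237.5 mm³). ROI placements are rejection-sampled (seeded) so that
  the sphere plus a 1 mm margin lies wholly inside the target compartment;
  the margin keeps wavelet edge responses from neighbouring compartments out
  of the ROI.

## Feature extraction (842 features)

Seven classes on the original image — shape (14), first order (18), GLCM
(23), GLRLM (16), GLSZM (16), GLDM (14), NGTDM (5) — plus the six non-shape
classes on each of eight wavelet sub-bands: 106 + 8 × 92 = 842. Names follow
`<filter>_<class>_<feature>` (`original_firstorder_Mean`,
`wavelet-LLH_glcm_Contrast`).

Conventions, all IBSI-compatible and fixed so results are bit-reproducible:

* **Neighbourhood** — full 26-connectivity; GLCM and GLRLM accumulate over
  the 13 unique direction vectors at distance 1 and average *feature values*
  over directions (matrices are not merged). GLSZM zones are 26-connected
  components of equal level. GLDM dependence counts the 26-neighbours within
  `alpha = 0` of the centre level; feature formulas index dependence size
  `j = count + 1` so small-dependence emphases never divide by zero. NGTDM
  uses the mean level of the in-ROI 26-neighbours; voxels with no in-ROI
  neighbour are excluded.
* **Wavelet** — single-level undecimated separable Coiflet-1 analysis bank
  (low/high-pass per axis, symmetric boundary), so all 8 bands live on the
  input grid and the original mask applies unchanged.
* **Shape** — surface mesh by marching cubes at the 0.5 iso-surface of the
  zero-padded binary mask; MeshVolume by the signed-tetrahedron sum,
  SurfaceArea by triangle summation. Binary-mask marching cubes
  overestimates the area of smooth objects by a few percent (staircase
  facets), so Sphericity of digitised balls plateaus near 0.92 rather than
  1; MeshVolume converges to the analytic volume (within 2% at 0.1 mm for a
  2 mm-radius ball). Axis lengths are `4·sqrt(λ)` of the voxel-coordinate
  covariance eigenvalues; 2-D diameters are maximal distances of the mesh
  vertices projected onto each coordinate plane. Single-voxel masks have no
  meaningful mesh: mesh-based entries return a 0.0 sentinel with a warning.
* **Degenerate ROIs** — features whose definitions divide by zero on
  single-level ROIs return documented sentinels: 0.0 in general
  (Correlation, Busyness, InverseVariance, NGTDM Contrast/Complexity/
  Strength), Coarseness capped at 10⁶, MCC = 1 on a single-level ROI.
* **First order** — population moments, uncorrected Kurtosis; Entropy and
  Uniformity on the discretised histogram; percentiles by linear
  interpolation.

Every matrix-family feature is verified against an independent brute-force
enumeration (explicit loops over pairs, runs, zones and neighbourhoods) on
100 random ≤5³ ROIs per family.

## Reliability statistics

Repeatability uses the two-way mixed-effects, absolute-agreement,
single-measures ICC(A,1); reproducibility uses the average-measures ICC(A,k)
on scan/rescan-averaged values with the parameter settings as raters
(McGraw–Wong formulation):

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))
    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

95% CIs use the F-distribution method: Satterthwaite-approximate F for the
single form, Spearman–Brown transform of the single-form bounds for the
average form. Estimates and CIs are cross-checked against an independent
implementation in the tests; simulation shows mean recovery of a true ICC of
0.8 within ±0.03 (n = 50, k = 2, 200 replicates) and 93–97% CI coverage
(n = 30, k = 2, 500 replicates). Numerical edge cases: an all-identical
matrix returns ICC 1 with degenerate CI [1, 1] and a degenerate flag;
strongly negative ICCs can drive the Satterthwaite df toward zero, in which
case the affected bound falls back to ±1.

**Classification.** A feature is *reliable* when ICC > 0.8 and *highly
robust* when additionally the lower 95% bound exceeds 0.7 — strict
inequalities in both. Constant-valued features have no defined ICC; they are
flagged degenerate and excluded from reliable/robust counts (shape features
are degenerate by construction in scan–rescan screening, since the mask does
not change — mirroring the practice of excluding shape from repeatability
analysis).

**Subjects in the phantom design.** A single phantom has no natural
"subjects"; here subjects are repeated seeded ROI placements (default 10)
within the soft-tissue compartment, and raters are scan/rescan. Between-
subject variance then comes from the frozen texture sampled at different
locations, rater variance from acquisition noise, so the per-feature ICC is
a meaningful noise-vs-texture signal ratio. The placement count is
configurable.

**Volume correlation.** Pearson r of each original (unfiltered) feature
against `original_shape_MeshVolume` over the five segmentation volumes; a
feature is flagged when r > 0.8 — the signed rule, as the convention prints
it; an `absolute=True` option flags |r| > 0.8 instead. Constant features are
recorded degenerate and never flagged.

**Cohort comparison.** Paired two-tailed t-tests (n = 9 index-paired
subjects) on the features robust in both arms, significance at p < 0.05 with
no multiplicity correction by default (a Benjamini–Hochberg option exists).
With independent null features the empirical false-positive rate is ≈5%, as
the tests verify; real radiomics features are strongly correlated, so the
realised fraction in any single pipeline run is more variable.

## Study defaults and problem sizes

The default study uses a 64³ grid at 0.26 mm isotropic (the native slice
spacing; the in-plane value is assumed equal since only the slice spacing is
published), 10 ROI placements, energies {40, 50, 60} kV, bin widths
{10, 25, 50, 100}, slice thicknesses {0.2, 0.26, 0.3, 0.5, 1.0} mm, volumes
{27.68, 34.38, 41.71, 92.24, 237.5} mm³, a 42 mm³ ROI for the texture study
and the 60 kV / bin 25 / 0.26 mm reference workflow. The test suite shrinks
grids to 48³ and placements to 4–6; these sizes were chosen so the full
suite and the acceptance script each run in minutes on one CPU, and they are
the package's documented simulation sizes, not tuned quantities.

## What passing tests do and do not show

The generators emulate compartmentalised density-calibrated volumes,
test–retest noise, energy-dependent noise/contrast/bias, and two-arm texture
differences. They do not emulate CBCT projection physics, beam hardening,
scatter, reconstruction artefacts, partial-volume effects at real tissue
interfaces, or anatomical variability. Passing the pipeline tests therefore
demonstrates that the *statistical machinery* — extraction determinism, ICC
estimation, classification, screening logic — behaves correctly under
controlled conditions; it does not certify that any particular feature is
robust on real scanner data, and the synthetic robust-feature counts are not
comparable to counts measured on physical phantoms. Known limitations:
Gaussian noise only (no Poisson/streak components), staircase bias in
mesh surface area, and a single-phantom "subjects = placements" ICC design
whose between-subject variance is texture-driven rather than biological.
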