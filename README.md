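# cbctrad

**Preclinical CBCT radiomics: digital phantoms, IBSI-style 3-D feature
extraction, and ICC-based robustness screening.**

Small-animal irradiators carry onboard cone-beam CT (CBCT), and the scans
they produce are rich enough for radiomics — high-throughput extraction of
quantitative texture descriptors that may act as imaging biomarkers. But
radiomics features are notoriously sensitive to the workflow that produces
them: imaging energy, intensity discretisation, slice thickness and
segmentation volume all change which features are trustworthy. `cbctrad` is
a library for studying exactly that, end to end and fully in silico: it
generates density-calibrated digital phantoms and scan–rescan pairs, extracts
an 842-feature radiomics vector, and screens features for repeatability and
reproducibility with mixed-effects intraclass correlations.

It is aimed at preclinical imaging scientists who want to stress-test a
radiomics pipeline — or validate their own extraction and screening code —
without scanner time or animal data.

## The statistics at the core

**Features.** 842 features per ROI: shape (14), first order (18), and the
five gray-level texture-matrix families GLCM (23), GLRLM (16), GLSZM (16),
GLDM (14), NGTDM (5) on the original image, plus the six non-shape classes
on each of 8 wavelet sub-bands (106 + 8 × 92 = 842). Intensities are
discretised with a fixed bin width *w* anchored at the ROI minimum,
`level(x) = ⌊(x − min)/w⌋ + 1`; texture matrices use the 26-neighbourhood
with feature values averaged over the 13 unique 3-D directions. Every
matrix-family feature is verified against independent brute-force
enumeration in the test suite.

**Reliability.** For an n-subjects × k-raters measurement matrix with
two-way ANOVA mean squares MSR, MSC, MSE, the package computes the
absolute-agreement intraclass correlations

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))
    ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

with F-based 95% confidence intervals. A feature is **reliable** when
ICC > 0.8 and **highly robust** when additionally the lower 95% bound
exceeds 0.7. Scan–rescan repeatability uses ICC(A,1) with ROI placements as
subjects and scan/rescan as raters; across-setting reproducibility uses
ICC(A,k) on scan-averaged values with the parameter settings as raters.
Features with Pearson r > 0.8 against mesh volume are flagged as
volume-driven, and two tumour cohorts are compared feature-by-feature with
paired two-tailed t-tests (p < 0.05).

## A worked example

```python
from cbctrad import (DEFAULT_PROTOCOLS, extract_all, generate_mouse_phantom,
                     make_spherical_mask, sample_roi_centres, simulate_scan_pair)

img, labels, _ = generate_mouse_phantom(seed=7)
scan, _ = simulate_scan_pair(img, DEFAULT_PROTOCOLS[60], seeds=(1, 2))
centre = sample_roi_centres(labels, img.grid, 92.24, n=1, seed=3)[0]
fv = extract_all(scan, make_spherical_mask(img.grid, centre, 92.24))
```

prints, via `examples/02_extract_features.py`:

```
extracted 842 features from a 92.1 mm³ ROI (5241 voxels)
  original_shape_MeshVolume                 91.7248
  original_firstorder_Mean               16865.6136
  original_glcm_Contrast                   140.9156
  original_ngtdm_Coarseness                  0.0016
  wavelet-HHH_firstorder_Variance        29926.5537
```

The mesh volume tracks the requested 92.24 mm³ segmentation; the first-order
mean sits at the soft-tissue calibration (16,844 scanner units) plus scan
noise; the GLCM contrast and NGTDM coarseness quantify the ROI's texture.
Screening those features across imaging energies
(`examples/03_icc_screening.py`, reduced 48³ study) gives

```
 condition  n_reliable  n_robust  n_degenerate
        40          16        14             0
        50          41        17             0
        60          41        20             0
robust features shared by all energies: 14
```

— the noisy 40 kV protocol supports the fewest reliable features and the
clean 60 kV protocol the most, with a small energy-invariant core. The other
examples cover phantom generation (`01`), the segmentation-volume effect and
volume-correlation filtering (`04`), and the two-arm tumour-cohort pilot
(`05`); each prints its numbers with a note on what they mean.

A thin CLI mirrors the library: `cbctrad fixtures | extract | repeatability |
volume-effect | reproducibility | texture | cohort` (see `--help`).

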