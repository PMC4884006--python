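# Methods

## Overview

`lungcv` quantifies ventilation heterogeneity in reconstructed lung-SPECT
volumes. The local measure is the coefficient of variation (CV) of voxel
counts in a small cubic neighbourhood; a subject is summarized by the
normalized distribution of their CV values (the *density curve*) and by
the area of that curve above a CV threshold, AUC(CV > CV_T). Because CV
values from healthy tissue scale with the inverse square root of the
local count level, curves from subjects with different tracer uptake are
made comparable by a two-step compensation before thresholding.

## Pipeline stages and their assumptions

### Lung segmentation

The lung is segmented from the co-registered attenuation map by
thresholding: voxels attenuating strictly below 0.12 cm⁻¹ while lying
inside the body (attenuation > 0) are lung candidates. At 140 keV,
aerated lung (~0.05 cm⁻¹) and soft tissue (~0.15 cm⁻¹) straddle this
threshold comfortably. Component cleanup keeps the largest candidate
component, plus a second whose size is at least 25 % of the largest (the
two lungs may be disconnected on the grid). The procedure is fully
automatic; there is no manual mask editing.

The inner/outer partition erodes the mask three times with the
face-connected (6-neighbour) structuring element; the inner volume is
the erosion result and the outer volume the set difference. At 3.45 mm
voxels the three-voxel shell is ≈1 cm deep; on the default phantom the
outer shell holds ≈52 % of the lung volume, similar to the 50–60 %
reported for adult subjects. The structuring element and erosion depth
are recorded in mask provenance so alternatives remain comparable.

### CV mapping

Each lung voxel receives
`CV = 100 · s / m` (percent), with `m` the mean and `s` the sample
(n−1) standard deviation over the 3×3×3-voxel cube centred on it —
a 1.04 cm cube (≈1.1 cm³), the closest odd-sided cube to 1 cm³ at this
voxel size. Design choices that matter:

* **Windows are not restricted to the mask.** At the boundary the cube
  straddles the resolution-driven activity fall-off, which is precisely
  what produces the high-CV rim (the periphery/edge effect). Restricting
  windows to in-lung voxels would suppress a real feature of the data;
  the rim is handled downstream (inner/outer decomposition), not hidden.
  The rule is recorded in the CV matrix provenance.
* Windows truncated by the image border use only in-grid voxels.
* Voxels whose window mean is ≤ 0 are flagged undefined (NaN), counted,
  and excluded from density curves.
* Numerics: window sums come from a separable box filter; variance
  residue below `1e−12 · mean²` (cancellation error of the separable
  sums) is clipped to zero so constant regions report exactly CV = 0.

For independent Poisson counts of mean λ the window CV concentrates near
`100 / sqrt(λ)`; this count-level dependence is the reason compensation
is needed, and is verified directly in the tests.

### Density curves

CV values are histogrammed on a fixed-width grid (default 0.5 CV%)
starting at 0, and converted to density in percent per CV% so that the
rectangle-rule area is exactly 100 %. A histogram rather than a kernel
estimator keeps the construction deterministic and oracle-friendly; the
bin width is exposed in the configuration. At least 100 finite values
are required.

The *mode* is the bin centre of the global maximum after a 3-bin moving
average (edge bins renormalized), ties breaking toward lower CV. The
*left-flank crossing* of a density level is found by scanning bins from
zero up to the mode and interpolating linearly between the bracketing
bin centres; curves already above the level at the first bin return the
first bin edge and are flagged in provenance.

### Compensation

Two normalizations are provided:

* **Mode-ratio transform** (`mode_ratio_transform`): multiply all CV
  values by `M_target / M_source`. Exact for uniform activity
  distributions at different count levels, but it stretches the
  heterogeneity tail, so applying it to subjects distorts exactly the
  signal of interest.
* **Two-step compensation** (`compensate`), used for subjects:
  1. *Shift*: locate the CV where the curve's ascending left flank
     reaches the fix-point density (0.5 % per CV% at 3 CV%) and add
     `shift = 3 − crossing` to every CV value. The shift is negative for
     subjects whose healthy regions carry a lower activity concentration
     than the reference norm. Negative shifted values are clipped to 0
     and counted in the record.
  2. *Rescale*: multiply the shifted values by
     `M / (M − shift)` with the reference mode `M = 9.5` CV%.

  The value-level reading is used throughout: the shift and rescale are
  applied to the CV values themselves and the curve is rebuilt, rather
  than manipulating only the plotted curve.

The constants (fix point at (3, 0.5), reference mode 9.5 CV%) are the
published reference values derived from healthy human curves and are
kept as fixed defaults. `derive_norm_mode` can re-derive the reference
mode from a user-supplied reference cohort as the fixed point of the
compensate → mean-curve → mode map, which is the self-consistency
property the reference mode must satisfy.

**Reliability limit.** The compensation assumes a healthy lung volume
large enough to form a distinct peak whose flank reflects the healthy
count level. When the count level is too low, the curve becomes a
symmetric bell, the heterogeneity tail is lost in noise, and the
compensation over-corrects — the compensated AUC can drop *below* the
healthy reference, a misleading result. A configurable exclusion limit
flags runs with `|shift| > 3` CV%; flagged values are still returned,
with a warning.

**Synthetic norm vs human constants.** The fix point and mode describe
*human* curves, which are broadened by genuine tissue heterogeneity,
breathing motion and reconstruction filtering. The phantom's pure-Poisson
curves are much narrower: at the default 50 expected counts per lung
voxel the interior CV sits near 14 % and the flank crossing near 9.5 %,
so even healthy phantoms carry shifts around −6 CV% and trip the
exclusion flag. This is a faithful consequence of pairing the
human-derived constants with an idealized noise model, not a defect of
either; simulation studies that need the compensation in its reliable
regime should use count levels ≳150 per voxel (the demo cohort does).

A related caveat: the two-step compensation maps a curve's mode onto
9.5 CV% only when the curve already resembles the norm
(`mode = 9.5 − 2·shift`); it is deliberately milder than the mode-ratio
transform. The mildness inequality
`|scale_factor − 1| ≤ |M_target/M_source − 1|` holds for uptake-scaled
families anchored at the fix point — verified on a clipped
Normal(9.5, 2.48) family, whose density curve passes through the fix
point — but can reverse for narrow curves far from the norm shape.

### Heterogeneity statistics

`auc_above` integrates the density curve above a threshold by the
rectangle rule, splitting the boundary bin linearly. Thresholds 9.5 CV%
(reference-curve mode) and 20 CV% (approximately where patient curves
intersect the reference mean curve; wider dynamic range across subjects)
are exposed as named constants; arbitrary thresholds are accepted. No
attempt is made to re-derive the 20 % intersection from data — that
requires real patient curves — and no hot-spot exclusion is performed.

The inner/outer decomposition histograms each partition's CV values on
the full curve's bin grid, scaled by the *total* value count, so the two
component densities sum bin-wise to the full curve and their areas equal
the partitions' volume shares of 100 %.

### Association statistics

Ordinary least squares of AUC(CV > CV_T) on one covariate at a time
(statsmodels), reporting Pearson r, the slope with t-based 95 % CI, r²,
the two-sided p and n. Covariates enter in raw units (not % predicted).
The group comparison regresses on a 0/1 indicator, so the slope is the
group mean difference. Residual normality (Shapiro–Wilk) and
homoscedasticity (Breusch–Pagan) are emitted as a report, not enforced.
No multiple-testing correction is applied. The packaged
15-subject characteristics table carries integer-rounded AUC values, so
recomputed correlations match the published ones to ≈±0.02.

## The digital phantom

The phantom exists so that every downstream stage is testable without
gamma-camera data. It reproduces the *statistical* structure the
analysis depends on, not anatomy:

* two ellipsoidal lungs (half-axes 32×45×75 mm, centres ±45 mm) inside
  an ellipsoidal soft-tissue body, voxelized at 3.45 mm;
* two-valued, noiseless attenuation (0.15 / 0.05 cm⁻¹) straddling the
  segmentation threshold; CT noise is out of scope;
* uniform tracer concentration in healthy lung, optionally reduced
  inside spherical defects (`activity_fraction` ∈ [0, 1));
* acquisition emulated by a stationary Gaussian PSF (default FWHM
  12 mm), which reproduces the periphery effect with one interpretable
  parameter, followed by independent Poisson noise per voxel. The ~90 MBq
  deposit of the imaging protocol maps to a default of 50 expected counts
  per lung voxel; the pipeline only ever sees reconstructed counts, so
  counts-per-voxel is the natural parameterization.

What the phantom does **not** emulate: photon transport and scatter,
iterative reconstruction and its correlated noise, post-filtering,
breathing motion, the posture-dependent posterior "rind", airway hot
spots, or genuine parenchymal heterogeneity. Passing tests therefore
demonstrate the correctness and internal consistency of the analysis
chain under the stated noise model — not clinical performance on real
acquisitions.

Geometry validation uses conservative sufficient bounds (sampled surface
points for lung-in-body; `‖c/a‖₂ + r/min(a) ≤ 1` for sphere-in-lung), so
a valid spec is guaranteed consistent, at the price of rejecting some
marginally-fitting geometries.

Cohort generation derives one independent random stream per member from
the master seed, records all generating parameters in the metadata table
for parameter-recovery tests, and supports an age-linked defect burden
for association studies.

## Numerical and design choices

* Sample (n−1) standard deviation in CV windows, so the hand/brute-force
  oracle matches exactly.
* Histogram grids always start at 0; a value exactly on the last edge
  gets its own bin, keeping every value interior to a bin.
* `find_mode` ties break toward lower CV (first argmax).
* Negative compensated CV values are clipped to 0 and counted.
* Mean curves require a common bin width; shorter curves are zero-padded
  (all grids share the origin), then the average is renormalized to
  100 %.
* Problem sizes in tests and in the acceptance script: 64³ default
  phantoms (~22 000 lung voxels), 48³ reduced phantoms for
  simulation-heavy properties, 40³ uniform Poisson fields (~55 000 CV
  values) for curve statistics, and a 96³ uniform field (~7.8×10⁵ CV
  values) where flank-level precision of ~2 % is needed. These sizes give
  sampling noise comfortably below the tested tolerances.
* The mode-ratio collapse test tolerance was calibrated by simulation:
  across seeded replicates the same-procedure sup-distance stays below
  8 % per CV% (dominated by bin-centre mode quantization) while the raw
  curve separation is ≈31; the test also requires the collapse to close
  at least 70 % of the raw separation.

## Known limitations

* The compensation inherits the reliability limit described above; the
  exclusion threshold (default |shift| > 3 CV%) is a pragmatic flag, not
  a validated decision rule.
* Segmentation assumes co-registered emission/attenuation volumes and
  performs no airway removal or left/right labelling.
* The published per-subject AUC values and curve shapes cannot be
  reproduced from this package alone — they require the original
  acquisitions; only the subject-table associations are recomputable.
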