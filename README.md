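# lungcv

Quantitative ventilation-heterogeneity analysis for lung SPECT.

Uneven ("patchy") ventilation is an early functional signature of airway
narrowing and air trapping in smokers, allergic subjects, asthmatics and
COPD patients — sometimes detectable before conventional lung function
tests deviate from normal. Given a reconstructed ventilation volume
(e.g. inhaled ⁹⁹ᵐTc-Technegas counts) and a co-registered attenuation
map, this package:

1. segments the lung by attenuation thresholding (μ < 0.12 cm⁻¹ inside
   the body) and splits it into an inner core and a ~1 cm outer shell;
2. maps local heterogeneity as the **coefficient of variation**
   `CV = 100 · s/m [%]` over overlapping ~1 cm³ cubic windows
   (3×3×3 voxels at 3.45 mm), producing a 3D CV matrix;
3. summarizes each subject as a **density curve** — the normalized CV
   distribution, in % per CV%, with total area 100 %;
4. **compensates** for subject-to-subject variation in tracer uptake by
   shifting each curve's left flank through the fix point (density
   0.5 % per CV% at 3 CV%) and rescaling the shifted CV values `A` by
   `A_compensated = A_shifted · 9.5 / (9.5 − shift)`,
   9.5 CV% being the mode of the healthy reference mean curve;
5. scores heterogeneity as **AUC(CV > CV_T)** — the area of the density
   curve above a threshold (reference thresholds 9.5 and 20 CV%); and
6. relates the scores to covariates by univariate OLS (Pearson r, slope
   with 95 % CI, r², p) and a two-group comparison.

Because clinical acquisitions are rarely shareable, the package includes
a **digital two-lung phantom** (uniform activity, optional spherical
defects, Gaussian system-resolution blur, Poisson counting noise) that
reproduces the statistical structure the analysis depends on — including
the spurious high-CV rim at the lung boundary (the periphery effect) —
so the entire pipeline is testable and demonstrable offline. It is aimed
at medical physicists and imaging researchers working on quantitative
ventilation SPECT.

## Worked example

```python
import numpy as np
from lungcv import (PhantomSpec, make_anatomy, make_activity, simulate_acquisition,
                    segment_lung, split_inner_outer, compute_cv_matrix,
                    estimate_density, compensate, auc_above)

spec = PhantomSpec(mean_counts_per_lung_voxel=200.0, seed=42)
attenuation, truth = make_anatomy(spec)
counts = simulate_acquisition(make_activity(truth, spec), spec)

mask = segment_lung(attenuation)                  # 0.12 cm^-1 threshold
inner, outer = split_inner_outer(mask)            # 3-voxel erosion
cv = compute_cv_matrix(counts, mask)              # 3x3x3 windows, CV in %

values = cv.cv_values()
compensated, record = compensate(values)          # fix-point shift + rescale
curve = estimate_density(compensated)

print(f"lung voxels: {mask.n_voxels}, outer shell: {outer.n_voxels / mask.n_voxels:.0%}")
print(f"median CV inner/outer: {np.median(cv.cv_values(inner)):.1f} / "
      f"{np.median(cv.cv_values(outer)):.1f} %")
print(f"shift: {record.shift:+.2f} CV%, scale factor: {record.scale_factor:.3f}, "
      f"excluded: {record.excluded}")
print(f"curve area: {curve.area:.1f} %")
print(f"AUC(CV > 9.5%): {auc_above(curve, 9.5).auc_percent:.1f} %")
print(f"AUC(CV > 20%):  {auc_above(curve, 20.0).auc_percent:.1f} %")
```

prints

```
lung voxels: 22016, outer shell: 52%
median CV inner/outer: 7.3 / 24.8 %
shift: -1.59 CV%, scale factor: 0.857, excluded: False
curve area: 100.0 %
AUC(CV > 9.5%): 46.2 %
AUC(CV > 20%):  26.0 %
```

Reading the numbers: the lung segmentation recovers ~22 000 voxels, half
of them in the outer shell. The interior of this *healthy, uniform*
phantom sits at CV ≈ 7 % (pure Poisson noise at 200 counts/voxel) while
the boundary shell reads CV ≈ 25 % — that is the periphery effect of
finite scanner resolution, not real heterogeneity. The compensation
finds this subject's flank 1.59 CV% right of the fix point (slightly
lower effective uptake than the norm) and rescales accordingly; the
resulting AUC(CV > 20 %) ≈ 26 % is baseline rim signal that any healthy
subject of this geometry produces.

A one-command demonstration cohort — 13 "healthy" members with an
age-linked mild defect burden plus 2 "patients" with a heavy burden —
runs the whole chain and the association stage:

```bash
lungcv demo --out demo_out --seed 1
```

Patients separate cleanly (AUC(CV > 20 %) ≈ 38–39 % vs 23–29 % for the
healthy members), the defect burden is recovered with r ≈ 0.91, and the
group comparison gives p ≈ 1e-7.

The `lungcv` CLI also exposes each stage separately — `phantom`,
`segment`, `cvmap`, `density`, `auc`, `regress`, and `run` for a full
YAML-configured pipeline over NIfTI volumes; see `lungcv --help`.

The packaged 15-subject characteristics table (13 healthy subjects, 2
patients with documented airway disease, with published AUC values)
drives the statistics layer:

```bash
lungcv regress --x height_cm --y auc_gt_20
# auc_gt_20 ~ height_cm: r=-0.831 b=-0.636 (95% CI -0.919, -0.353) r2=0.690 p=0.0004375 n=13
```

## Layout

```
src/lungcv/
  phantom.py        digital phantom: anatomy, activity, acquisition, cohorts
  segmentation.py   attenuation-threshold lung mask, inner/outer split
  cvmap.py          sliding-window 3D CV matrix
  density.py        density curves, mode/flank, compensation (shift + rescale)
  metrics.py        AUC(CV > CV_T), inner/outer curve decomposition
  stats.py          OLS associations, group comparison, subject table
  pipeline.py       YAML-configured end-to-end runs, demo cohort
  cli.py            `lungcv` command-line interface
  plotting.py       tri-colour CV slices, curve overlays
  data/table1.csv   subject characteristics fixture
docs/methods.md     model, assumptions, parameters, limitations
scripts/acceptance.py
tests/
```
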