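# osteotex

Noninvasive estimation of bone stiffness from CT images. The package
implements a complete, testable pipeline that connects the spatial texture of
trabecular bone in CT cross-sections to its Young's modulus:

1. **CT ingestion** — read HU volumes (DICOM series or TIFF stacks), sample
   cross-sections at fixed fractional positions along the bone axis, and
   build a bone region of interest as an HU window (default 250–1000 HU).
2. **Texture features** — mask-aware grey-level co-occurrence matrices
   (GLCM) at 0°/45°/90°, displacement 1, averaged, then the five
   second-order statistics: energy ΣP², entropy −ΣP log P, contrast
   Σ(i−j)²P, homogeneity ΣP/(1+(i−j)²), and correlation
   (Σ ij·P − μxμy)/(σxσy). Together with the ROI mean HU these form a
   six-element feature vector per cross-section.
3. **Mechanical calibration** — the flexural modulus from three-point
   bending, E = (F/Δ)·L³/(48 I), ash density from incineration data, and a
   density–modulus power law E = a·ρᵇ. The 15-specimen rabbit-femur
   calibration E = 2.098247·ρ^0.126871 ships as a packaged fixture, and the
   human cortical law E = 3.891·ρ^2.39 is carried alongside.
4. **Modulus network** — a from-scratch 6–N–1 tan-sigmoid backpropagation
   regressor (batch gradient descent with momentum, validation early
   stopping, 70/15/15 split) mapping the six features to a normalized
   modulus, with a hidden-size parametric study.
5. **Synthetic phantoms** — thresholded Gaussian-random-field trabecular
   slices with controllable bone-area fraction (the 2-D BV/TV analogue) and
   a known feature→modulus ground truth, so every stage is testable without
   scan data.

The intended users are biomechanics and medical-image-analysis researchers
who need patient-specific modulus estimates for finite-element models or
implant planning, without destructive mechanical testing.

## Worked example

```python
import osteotex as ot

# Evaluate the rabbit calibration against its own specimen table
report = ot.calibration_report(ot.RABBIT_LAW, ot.table4_fixture(as_records=True))
print(report.table.head(5).to_string(index=False))
```

```
specimen_id  ash_density  e_measured  e_predicted  residual
          1         0.74      2.4637     2.019603  0.197223
          2         0.71      1.6840     2.009026  0.105642
          3         0.50      1.7633     1.921607  0.025061
          4         0.84      2.1920     2.052343  0.019504
          5         0.63      0.5100     1.978786  2.157331
```

`e_predicted` is the power-law modulus at each specimen's ash density
(MPa); `residual` is the squared difference from the bending-test
measurement. Specimen 5 (which slipped off its support during loading)
dominates: its residual, 2.157, is two orders of magnitude above the
median, and `report.sensitivity` shows the aggregate standard error drops
from 0.544 to 0.375 when it is excluded.

```python
# Texture features of one synthetic trabecular slice
slc, truth = ot.make_trabecular_slice(ot.PhantomParams(bone_area_fraction=0.45, seed=7))
roi = ot.extract_roi(slc)            # 250-1000 HU bone window
print(ot.feature_vector(roi))
# FeatureVector(energy=0.0599, entropy=4.4748, contrast=0.8076,
#               homogeneity=0.7007, correlation=0.8688, mean_hu=508.54)
```

The realized bone-area fraction is 0.450 (target 0.45), and the mean ROI HU
of ~509 sits in the trabecular-to-cortical range.

```python
# End-to-end: 300-slice phantom cohort -> network, hidden-size sweep
df = ot.make_specimen_cohort(300, law=ot.HUMAN_LAW, noise_sd_e=0.05, seed=42)
x = df[list(ot.FeatureVector.FIELDS)].to_numpy(float)
cfg = ot.TrainConfig(max_epochs=2000, learning_rate=0.05,
                     max_validation_failures=100, seed=42)
table, best = ot.parametric_study(x, df.e_true.to_numpy(), [10, 20, 30, 40, 45], cfg)
print(best.metrics["test"].r)   # 0.9885 — held-out correlation, 45 test samples
```

The same stages are scriptable from the shell (`osteotex synth`,
`features`, `calibrate`, `train`, `predict`); see `osteotex --help`.

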