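# Methods

## Problem and model

Bone stiffness (Young's modulus, E) governs fracture risk and the mechanical
fit of implants, but measuring it directly requires destructive testing.
The modulus correlates both with mineral density and with trabecular
microarchitecture, and both are visible in CT: density through the mean
Hounsfield unit (HU) of a bone region, architecture through the spatial
arrangement of grey levels. This package estimates E from six CT image
properties — five second-order texture statistics of the grey-level
co-occurrence matrix (GLCM) plus the mean ROI HU — using a small
backpropagation network, anchored to a density–modulus power law calibrated
on three-point-bending and ash-test data.

## ROI and cross-section sampling

A specimen volume is reduced to `n_slices` cross-sections (default 10) at
fractional positions linearly spaced over `[lo_frac, hi_frac]` (default
5%–95% of the stack), which avoids the epiphyses where cross-sections change
shape rapidly. A fraction maps to a slice index by `round(frac·(N−1))`,
ties rounding half up; the mapping is a package convention, chosen to be
symmetric about mid-stack.

The ROI is defined purely radiometrically: all pixels whose CT number falls
in the closed HU window `[250, 1000]` (configurable; a wider population
window of roughly 200–1200 HU spans marrow through dense cortical bone).
All in-window pixels are used, connected or not — no morphological
post-processing. HU statistics over the ROI use the sample SD (n−1); a
single-pixel ROI reports SD 0.

## Texture features

Masked HU values are quantized to `Ng` equal-width grey tones (default
Ng = 8) over either the fixed HU window (default — makes tones comparable
across slices and specimens) or the per-slice ROI min/max. The top bin edge
is inclusive.

Co-occurrence matrices are computed at displacement 1 for the 0°, 45°, 90°
orientations — offsets (0, 1), (−1, 1), (−1, 0) in row/column coordinates;
135° is deliberately not included in the default set (the orientation list
is configurable). A pixel pair counts only when *both* pixels are inside
the mask, so ROI boundary pixels contribute fewer pairs and background
never leaks in. Matrices are symmetrized by default (each pair counted in
both orders), which makes the row and column marginals coincide so the
correlation feature's μx = μy. The per-orientation matrices are averaged
*before* feature evaluation (feature-of-average, not average-of-features).

Entropy uses log base 2 by default (bits; base e available) with
0·log 0 := 0. When a marginal SD is zero (constant ROI), correlation is
undefined; it is reported as 0 with an explicit `correlation_defined=False`
flag rather than raising, so a degenerate slice cannot abort a batch run.

Implementation notes: the GLCM accumulation is vectorized array shifting +
`bincount`; the test suite checks it against an exhaustive double-loop pair
counter (all offsets, masked and unmasked, random images up to 5×5 with
Ng ≤ 4, tolerance 1e−12) and against `skimage.feature.graycomatrix` on
full-mask images. skimage measures angles with the row axis pointing down,
so its 0/3π4/π2 angles equal this package's 0°/45°/90° offsets.

## Mechanical reduction and power-law calibration

* Flexural modulus: E = (F/Δ)·L³/(48·I), MPa for N/mm, mm, mm⁴ inputs.
* Ash density: implemented as (w1 − w2)/v1 (dry weight minus ash weight
  over volume), matching the convention used to produce the packaged
  calibration table; the conventional mineral density w2/v1 is available
  via `convention="ash-weight"`. The choice is a switch, not a guess,
  because the two differ materially and the fixture's convention governs.
* Power-law fit: default nonlinear least squares on the original scale
  (`scipy.optimize.curve_fit`, tolerances 1e−10), initialized at the
  closed-form log-log OLS solution; log-log OLS is also exposed. On exact
  power-law data both recover (a, b) to better than 1e−6. On the packaged
  15-specimen table the two criteria give different exponents and neither
  exactly reproduces the reference constants (2.098247, 0.126871) — the
  original fitting criterion is not recoverable from the table — so the
  reference law is shipped as a constant (`RABBIT_LAW`) and fits are
  reported alongside it, never asserted equal.
* Diagnostics: per-specimen residual is the squared difference
  (E_meas − E_pred)², matching the packaged table's residual column (13 of
  15 rows to ≤1e−3 relative; two rows carry ~1.3e−3 printed rounding
  noise). The aggregate standard error formula is configurable
  (`rms-n-2` default, i.e. sqrt(SSR/(n−2)); also `rms-n`, `rms-n-1`)
  because no single RMS-style formula reproduces the historically reported
  aggregate values; leave-one-out recomputation exposes single-specimen
  outliers.

## Network

Architecture: 6 inputs → N tanh hidden units → 1 tanh output. Weights are
initialized uniformly in [−1, 1] and biases in [0, 1], reproducibly per
seed. Since the output unit saturates at ±1, inputs and the target modulus
are min-max scaled to [−1, 1]; scalers are fitted on the training split
only, and predictions are mapped back to MPa through the inverse output
scaler. MSE metrics are reported on the normalized scale; Pearson R is
scale-invariant.

Training is classical backpropagation: full-batch gradient descent with
momentum (defaults: learning rate 0.01, momentum 0.9; the CLI and the
end-to-end benchmark use 0.05, which converges faster on the phantom
cohorts while remaining stable). The analytic gradients are verified
against central finite differences to <1e−6 relative on every parameter
group. Early stopping halts training after `max_validation_failures`
consecutive epochs without a new validation-MSE minimum (default patience
6; the benchmark uses 100), and the returned parameters are those of the
best-validation epoch. The 70/15/15 split uses floor sizes for training
and validation with the remainder to test, giving 210/45/45 at n = 300 and
7/1/2 at n = 10.

The hidden-size parametric study trains one network per candidate size
(same seed and config) and tabulates train/validation MSE and R; the best
size is chosen by validation R with ties going to the smaller network.

## Synthetic phantoms

`make_trabecular_slice` uses the standard thresholded-Gaussian-random-field
construction: smooth seeded white noise with a Gaussian kernel of width
`correlation_length` (pixels; sets trabecular structure scale, default 3),
threshold at the quantile realizing the target `bone_area_fraction` (the
2-D BV/TV analogue; realized fraction is exact up to pixel discreteness,
well within ±0.02 at 128²). Marrow pixels draw HU uniformly from
(−80, 200); bone pixels get HU in (300, 950) increasing with the field's
height above threshold normalized by the field SD — a partial-volume /
mineralization proxy that makes mean ROI HU increase monotonically with
bone fraction, as it does across real cancellous-to-cortical bone.
Additive Gaussian HU noise (SD 10) is clipped at ±4σ, so each phase stays
strictly inside its configured range and the 250–1000 HU window recovers
exactly the generated bone phase. These HU defaults put the cohort mean
ROI HU near 500, in the trabecular-bone range.

`make_specimen_cohort` couples each phantom to a ground-truth modulus:
apparent density is affine in the realized bone fraction
(ρ = 0.1 + 2.4·fraction, spanning 0.58–2.02 over the default fraction
range 0.2–0.8, bracketing the 0.42–1.97 calibration densities) and
E = law(ρ)·(1 + ε) with relative noise ε ~ N(0, noise_sd_e) truncated at
±4σ. All per-slice seeds derive from the cohort seed by a counter, so any
slice regenerates independently.

The generator's default target law is the rabbit calibration
(`RABBIT_LAW`). The end-to-end learnability benchmark, however, generates
targets from the human cortical law (`HUMAN_LAW`, exponent 2.39): with the
rabbit exponent of 0.127 the modulus varies by less than ±10% over the
entire density range, so 5% multiplicative noise caps the attainable
predicted-vs-true correlation near 0.6 for *any* regressor — the benchmark
would measure the noise floor, not the pipeline. Under the human law the
modulus spans roughly 1–21 MPa·(units as tabulated) and the 300-sample
cohort (5% noise, 70/15/15 split, hidden sizes 10–45) reaches held-out
R ≈ 0.94–0.99.

What the phantoms do *not* emulate: anatomically realistic femur geometry,
3-D connectivity, scanner physics (beam hardening, partial-volume blur
beyond the HU ramp, calibration-phantom drift), and inter-specimen
biological covariance. Passing the synthetic benchmarks therefore
demonstrates that the implementation recovers a known feature→modulus map
through the full image pipeline — not that the same accuracy transfers to
clinical scans.

## Numerical conventions and degenerate inputs

* GLCM probabilities must sum to 1 within 1e−9; averaging preserves this.
* A single-pixel or fully fragmented mask (zero valid pairs) raises
  `EmptyROIError`; batch drivers log and skip such slices and exit with a
  "partial" status (code 2).
* Constant ROI: quantizes to level 0, features hit the exact degenerate
  corner (energy 1, entropy 0, contrast 0, homogeneity 1, correlation
  flagged-0).
* Min-max scaler: a constant column maps to mid-range and inverts back to
  the constant.
* Training divergence (non-finite MSE) raises with the history attached.

## Problem sizes

The shipped tests and benchmarks use 128² phantoms (300-slice cohorts) and
networks up to 45 hidden units; these sizes give stable statistics — the
realized-fraction error is below 0.5% and the held-out R plateaus — while a
full suite run stays in the tens of seconds.

## Known limitations

* The packaged calibration's tabulated moduli (~2 MPa) are used exactly as
  tabulated; they are far below typical cortical-bone moduli, so absolute
  predictions inherit the fixture's unit convention.
* The historically reported aggregate standard errors for the rabbit law
  (0.1383 full; 0.023 excluding the outlier specimen) are not reproducible
  from the table by any standard RMS formula and are treated as metadata.
* Texture is strictly 2-D per slice; no volumetric co-occurrence.
* The optimizer is plain momentum gradient descent by design (it is the
  method being modelled); it is not the fastest way to fit such a network.
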