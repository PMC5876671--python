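# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of the package.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Reflectance calibration

Raw counts are converted to relative reflectance per pixel and band,
`I = (I0 − D)/(W − D)`, with `W` a white-board frame and `D` a dark-current
frame.  Frames may be full images, per-column vectors (line-scan convention)
or single spectra; they broadcast against the cube.  Two numerical guards:

* pixels with `W − D ≤ 10⁻⁶·max(W)` get reflectance 0 and are counted on the
  output (`n_degenerate`) — the measurement carries no information there;
* output is clipped to `[0, 1.5]`: specular highlights can legitimately
  exceed 1, values beyond 1.5 are treated as artifacts.  Clipping is logged,
  never an error.

The ENVI dialect is deliberately small: BSQ and BIL interleaves,
little-endian, unsigned 16-bit counts or 32-bit-float reflectance, and a
mandatory wavelength list.  BIP is rejected — line-scan VNIR instruments do
not emit it and supporting it would complicate the reader for no user.

## Synthetic scenes

The generator exists because no public litchi cubes accompany this kind of
study.  It emulates the *statistical structure* the analysis relies on, not
litchi biochemistry:

* **Wavelength grid** — 215 bands, 400 to 999.2 nm in 2.8 nm steps (the
  instrument resolution); 694 nm falls exactly on the grid, 725 and 798 nm
  within half a step.
* **Class spectra** — a logistic red-edge step near 685 nm plus a Gaussian
  green bump near 560 nm and a browning trough near 746 nm.  Damage age
  lowers the red-edge amplitude by 6 % per class and deepens the trough by
  0.025 per class, so consecutive class curves sit ≥ 0.05 apart at 725 nm.
  Per-sample jitter (≈1–3 % amplitudes, ±1.5 nm centers) emulates
  fruit-to-fruit variation and is deliberately smaller than the class gaps.
* **Damage blob** — a disc with low-order harmonic boundary roughness,
  carrying an extra reflectance depression at 746 nm of depth 0.06 / 0.10 /
  0.14 for the three damaged classes and doubled texture noise.  The
  newly-damaged depth is intentionally shallow: micro-damage is the hard
  case, and the segmentation results reflect that (below).
* **Noise** — independent per-pixel-band Gaussian noise, std 0.004 inside
  450–850 nm and tripled (0.012) outside, reproducing the "noisy shoulders"
  of VNIR spectra; spatially correlated texture (std 0.010, 3 px correlation
  length); a mild smooth multiplicative illumination field (std 0.01, 25 px).
  The illumination field is an addition beyond the minimal noise model —
  real captures always carry one — kept small because a strong gradient
  confounds intensity-based bruise clustering.
* **Raw counts** — the calibration model inverted:
  `I0 = D + (W − D)·R + noise`, with a smooth white frame near the gain
  (3000 counts per unit reflectance) and a dark frame near 1 % of it.
  Calibrating a sample with its own frames therefore recovers the rendered
  reflectance field exactly in the noise-free limit (a test asserts this).

What the generator does **not** emulate: absolute litchi reflectance values
(no published table exists to match), stem/calyx geometry, specularities,
multi-fruit frames, wavelength-dependent texture, or sensor nonlinearity.
Passing tests show the *methods* recover planted structure under realistic
noise; they say nothing about classification rates on real fruit.

## Spectra and PLS-DA

ROI spectra are 50 × 50-pixel means centered on the ground-truth damage
centroid (fruit centroid for fresh fruit) — the manual ROI placement of a
bench study, automated.  Preprocessing: Savitzky–Golay smoothing (window 11
bands, order 2 — common chemometrics defaults, config-exposed) with the
polynomial-interpolation end rule, so polynomials of degree ≤ order pass
through unchanged; baseline correction as per-spectrum minimum subtraction;
detrending as least-squares line removal over wavelength.  Spectra are
trimmed to 450–850 nm before modeling to drop the noisy shoulders.

PLS-DA regresses the single ordinal response y ∈ {0, 1, 2, 3} on
mean-centered spectra.  With one response the NIPALS weight step is closed
form per component (w ∝ Xᵀy), scores deflate X and y, and the coefficient
vector B = W(PᵀW)⁻¹q predicts in one product.  Ordinal coding (rather than
one-hot PLS2) matches the four ordered damage stages; nearest-code
assignment breaks exact midpoint ties toward the lower code (the less
damaged call).  The latent-variable count minimizes leave-one-out RMSE of
the coded response over 1..10, ties to the smaller count; each fold is
fitted once at full depth and evaluated at every truncation.  Unit-variance
scaling is off by default: reflectance already shares a scale across bands.

## PCA band selection

Fruit-masked pixels (pooled from one cube per class, subsampled to at most
50 000) are eigen-decomposed via their band covariance.  Contribution rates
use the full eigenvalue spectrum in the denominator; loading signs are fixed
so each column's largest-magnitude entry is positive.  Characteristic
wavelengths are local extrema of a chosen loading curve (PC3 by default)
after light SG smoothing (window 7), kept when their prominence reaches 5 %
of the curve's range — the threshold is a free parameter; the source study
reports three extrema but no criterion.  On synthetic data the pooled PC
basis orders as: PC1 the class/damage contrast direction, PC2 the flat
texture direction, PC3 the damage residual — so the PC3 score image shows
the bruise, which a test asserts (≥ 10 gray levels of contrast).

## Segmentation

Pipeline per gray image: histogram equalization (classic CDF mapping) →
Otsu threshold (256-bin between-class-variance maximization, ties to the
lowest threshold) → 8-connected components above an area floor → hole
filling (dark bruises fall below the fruit/background threshold and would
otherwise punch holes in the fruit mask) → Roberts cross-gradient edges
(binarized by a second Otsu pass) → fuzzy c-means (c = 2, m = 2) on the
*unequalized* intensities of the eroded fruit interior.  Clustering runs on
raw intensities because equalization, applied image-wide, stretches the
unimodal interior of an intact fruit into an artificial spread.

The lower-mean cluster is the damage candidate (bruises are dark at
694–798 nm).  It is accepted only if the centers separate by ≥ 8 gray
levels *and* the candidate covers ≤ 25 % of the fruit; otherwise the damage
mask is empty.  An intact fruit's unimodal intensities always split into
two large, barely separated clusters — the fraction rule is what makes
"no damage" a possible answer.  FCM initializes deterministically at the
25th/75th intensity percentiles (1-D); seeded random data points otherwise.
Coincident point/center pairs get crisp membership.

The default image for segmentation and texture is the 725 nm band on a
*fixed* reflectance scale (0–1 → 0–255).  A PC-score image is available
(`image_source: "pc:3"`), but score images are min–max stretched per image,
which erases the cross-sample gray-level differences the texture "mean"
feature carries; the fixed-scale band image keeps both the spatial and the
level information.

A detectability limit worth knowing: with the default shallow newly-damaged
depth, blobs at the small end of the size jitter are genuinely invisible to
two-cluster intensity clustering — the FCM global optimum prefers splitting
the bulk.  The per-class mean IoU on the default conditions is ≈ 0.64 for
newly damaged and ≈ 0.99 for the 2 h / 4 h classes (recomputed by the
acceptance script); raising the cluster count or adding spatial features
would be the natural extension.

## GLCM texture

Co-occurrence counts are accumulated over four directions (0°, 45°, 90°,
135°) at distance 1 on a 64-level linear quantization, counting only pairs
whose both ends lie inside the analysis mask, then symmetrized and
normalized.  These parameters are the common Haralick convention; the
source study names none.  The seven features use standard definitions
(entropy in natural log; "variance" is the GLCM marginal variance; "mean"
is the mask-region mean of normalized levels, the one feature that carries
absolute intensity).  Published feature tables for this workflow contain
correlation and homogeneity values outside the standard ranges of those
statistics, so their exact conventions are unrecoverable; the standard
definitions are used and those magnitudes are not reproduction targets.
With zero marginal variance the correlation is defined as 1 (degenerate
perfectly-correlated case, logged).

## LS-SVM

Each binary machine solves `[[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y]`
directly; the relative residual of that solve is stored on the model and
asserted ≤ 10⁻⁸ in the acceptance suite.  Features are standardized with
training statistics inside each machine — GLCM features span orders of
magnitude and an unstandardized RBF kernel degenerates.  Multiclass is
one-vs-one (6 machines for 4 classes) with majority voting, ties to the
smallest code; (γ, σ²) are searched on log grids (γ ∈ 10⁰..10⁴,
σ² ∈ 10⁻¹..10²) by stratified 5-fold CV accuracy.  CV folds are built on a
canonical (lexicographically sorted) sample order so the chosen grid point
does not depend on how the caller ordered the training rows.  The RBF
kernel is `exp(−‖x−x′‖²/(2σ²))`.

## Pipeline, sizes and determinism

`pipeline.run_all` executes: band selection (PCA on one cube per class) →
streamed simulate/calibrate/extract/segment/texture over the 120-sample
modeling set and the 80-sample external set → PLS-DA (stratified 60/40
split of the 120) → LS-SVM (same split of the texture features) → reports
and a manifest with SHA-256 hashes of every output.  Cubes are processed
one at a time, so peak memory stays near a single 120 × 120 × 215 cube.
The default scale (200 samples) runs in well under two minutes on one CPU;
it is the scale at which the acceptance metrics are quoted.  Every stage
draws its randomness from a child of the master seed
(`numpy.random.SeedSequence`), and reports are written with fixed float
formats, so a rerun with the same configuration and seed is byte-identical
— a test asserts this, and the manifest hashes make it auditable.

## Known limitations

* Synthetic spectra are qualitative stand-ins; no quantitative claim about
  real litchi transfers from these tests.
* Single fruit per frame; the multi-fruit frames of a conveyor application
  would need the component-filtering stage extended.
* The characteristic-band stage reports whatever extrema the data produce;
  on synthetic scenes the PC3 loading typically yields one dominant extremum
  near the red edge rather than three.
* Intensity-only FCM misses the faintest bruises (above); this is reported,
  not hidden, by the per-class IoU in `segmentation.csv`.
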