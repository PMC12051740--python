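# Methods

`mechspheroid` is a tested re-implementation of a Brillouin-microscopy
mechano-phenotyping analysis for multicellular spheroids: simulate
shift maps of normal (MCF10A-like, "M1") and metastatic (MCF10CA1h-like,
"M3") spheroid cross-sections over Days 2/5/8 of 3D culture, extract
morphological and mechanical features, compute core/periphery zonal
statistics, and quantify how much mechanical features improve normal-vs-
cancer classification. This note records the model, the defaults, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Forward physics

Brillouin scattering links the measured frequency shift to the elastic
longitudinal modulus:

    omega_B = (2 n / lambda) * sqrt(M' / rho) * sin(theta / 2)

with refractive index `n`, incident wavelength `lambda` (default 660 nm),
modulus `M'` (Pa), mass density `rho` (kg/m^3) and scattering angle
`theta` (180 degrees for a confocal backscattering geometry). For
water-like parameters (`M' = 2.2 GPa`, `n = 1.33`, `rho = 1000`) this
gives approximately 5.98 GHz. `modulus_from_shift` is the exact algebraic
inverse; the forward/inverse round trip is tested to a relative 1e-12
over `M'` in [0.1, 100] GPa. The analysis itself operates on shifts, not
moduli: shift is a validated stiffness proxy and inverting every pixel
would require per-pixel `n` and `rho` that no instrument provides.

## Synthetic-data generator

No image data are publicly deposited for this assay, so the generator is
a first-class, tested component that encodes the reported *structure* of
the measurements with full ground truth:

* geometry — a disk of per-spheroid radius `N(radius_mean, radius_sd)`,
  boundary perturbed by five low-order Fourier modes whose relative
  amplitude is `boundary_roughness`; optional radial Gaussian
  protrusions (cancer Day 8) of configurable count and length;
* zones — symmetric Gaussian noise in the core, moment-matched
  skew-normal noise (negative shape) in the periphery, blended over a
  ~3 px annulus at 40% of the equivalent radius to avoid a seam;
* background — Gaussian around 5.00 GHz.

Absolute shift levels are **invented**: only relative structure (group
orderings, zonal gradients, histogram asymmetry) is published for these
spheroids. Defaults sit in a water-adjacent band (background 5.00 GHz,
zone means 5.18-5.36 GHz, zone SDs 0.03-0.09 GHz) and are fully
configurable. The default phenotype table encodes:

* normal mean shift rising monotonically Day 2 -> 5 -> 8; cancer rising
  Day 2 -> 5 then falling by Day 8; normal above cancer every day;
* core mean above periphery mean (0.05 GHz zonal gradient);
* periphery SD above core SD; whole-spheroid SD rising for normal,
  rise-then-fall for cancer;
* negative periphery skewness, strongest for normal spheroids, with the
  normal line dipping at Day 5 and the cancer line growing steadily more
  negative — so cancer is consistently *less* left-skewed than normal;
* identical radius distributions for both lines (16/30/44 um mean at
  Days 2/5/8, 3/5/7 um SD), making projection area deliberately weakly
  discriminative;
* cancer Day 8 carries two ~3 um peripheral protrusions and slightly
  higher boundary roughness.

Between-spheroid variability is controlled by three jitter fields
(common mean offset, SD 0.03 GHz; log-normal SD scale factor, sigma 0.10;
periphery-skew jitter, SD 0.10). Without them, spheroids of a condition
would differ only by pixel-sampling noise and every group comparison
would be degenerate. Effect sizes were calibrated once, before any test
was run, against two published anchors: (i) every reported ordering
should be detectable at Welch p < 0.05 with >= 95% power at the
validation size of 40 spheroids per group per day, and (ii) the Day-8
classification study should land near the reported accuracy regime
(morphology-only ~74%, morphology+mechanics ~95%); with the defaults the
package obtains roughly 77% and 99% there — the gap, not the absolute
values, is the validated quantity. Periphery skewness targets stay
within the skew-normal representable range (|skewness| < ~0.995).

Determinism: per-spheroid seeds are `spec.seed + crc32("line:day:index")
mod 2^31`; identical (params, seed) gives bit-identical maps. Generated
shifts are stored at float32 precision so in-memory cohorts match their
TIFF round trips exactly.

What the generator does **not** emulate: 3D structure (single 2D slice),
optical point-spread blurring, spectrometer/Lorentzian-fit noise,
intra-spheroid lumens or medium pockets, Matrigel mechanics, and any
absolute shift calibration. Passing tests therefore demonstrate that the
pipeline recovers the encoded population structure from realistic 2D
maps — not that the specific default numbers describe real spheroids.

## Segmentation and morphology

Background-statistics thresholding: pixels at or below the
`background_quantile` (default 0.25) of the intensity histogram form a
background sample; the threshold is `mean + k_sigma * SD` (default
k_sigma 3) of the *untruncated* background. Because the sub-quantile
sample is an upper-truncated — and, at its low end, skew-tail
contaminated — slice of the background, the untruncated parameters are
recovered by fitting a truncated normal from the sample's median and
IQR (the quantile-ratio equation in the truncation depth is monotone,
so the root is unique). Cleanup: morphological closing (disk radius 2),
hole filling, largest connected component; masks below 50 px fail with
a `SegmentationError` carrying the threshold used.

Shape descriptors (coordinates are (row, col), 0-based, pixel centers on
the integer lattice):

* **area** — pixel count times pixel size squared (um^2);
* **circularity** — `4*pi*A/P^2` with the perimeter measured as the
  length of the subpixel 0.5-level boundary contour, resampled to 256
  equal arc-length points and smoothed with a 5-point circular moving
  average. Naive pixel-edge counting overestimates a disk's perimeter by
  ~13% (circularity ~0.78) and Crofton intercept counting is ~7% off on
  rectilinear shapes; the smoothed contour keeps disks within 2% of 1
  and squares/rectangles within ~0.03 of their closed forms, and is
  invariant under integer upsampling because the smoothing scale is
  relative to contour length. Values may exceed 1 by up to ~0.02.
* **solidity** — area over convex-hull area (exactly 1 for convex masks
  up to 0.01 rasterization tolerance);
* **aspect ratio** — major over minor axis of the second-central-moment
  ellipse (>= 1);
* **C.V. of hull radii** — population SD over mean of distances from the
  unweighted mask centroid to the convex-hull *vertices* (not a
  densified boundary), so any regular polygon or rectangle scores 0.

The centroid is the unweighted binary centroid throughout: geometry, not
stiffness, defines position.

## Mechanical features and zonal statistics

All moment statistics use the biased (divisor-N) convention, so the SD
is consistent with the skewness denominator
`S_k = m3 / m2^(3/2)`. Whole-spheroid statistics use masked pixels only.
The core is the set of mask pixels within `core_fraction` (default 0.4)
of the equivalent-circle radius `sqrt(A/pi)` from the centroid,
Euclidean distance, boundary pixels inclusive (`<=`); the periphery is
the complement within the mask. "Radius" is genuinely ambiguous for
irregular shapes; the equivalent-circle definition is simple and
reproducible, and a sensitivity test verifies that moving
`core_fraction` over 0.35-0.45 shifts zonal means only within a small
bound. Constant regions have undefined skewness and raise rather than
return 0.

## Classification study

Per day and per feature set (5 morphological features vs all 8), the
protocol is: 100 runs of reshuffled stratified 10-fold cross-validation
(1000 models per experiment); within each outer fold, features are
standardized on the training portion only, an exhaustive grid search
over an RBF support-vector machine (`C` in {0.1, 1, 10, 100}, `gamma`
in {0.001, 0.01, 0.1, 1}) is scored by inner stratified 5-fold accuracy
on the training portion (nested, never on the outer test fold), and the
refit model is scored on the held-out fold. Grid ties go to the first
entry in declared order. The report carries the mean and SEM of the
1000 fold accuracies plus recall/precision/F1 for the cancer class
pooled over all held-out predictions. F1 is always computed as the
harmonic mean `2PR/(P+R)`; zero-denominator cases are reported as
undefined (`None`), never as 0.

A subtlety the tests encode: cross-validated accuracy on a *single*
label-permuted dataset deviates from 0.5 by order `1/sqrt(n)` (the
dataset's idiosyncratic separability, including the known below-chance
"anti-learning" regime at small n), so the chance-level check averages
over many permutations and uses the SEM of the permutation means.

The 7:1:2 train/validation/test arithmetic uses `test = round(0.2 n)`,
`validation = floor(0.1 n)`, `train = n - val - test`, which reproduces
(118, 16, 34) at n = 168.

## Group statistics and report

Normal-vs-cancer comparisons use the unpaired two-tailed Welch t-test
with Satterthwaite degrees of freedom; across-day comparisons within a
line use one-way ANOVA with Tukey HSD post-hoc (Bonferroni-adjusted
pairwise Welch tests selectable via config — the post-hoc procedure is a
genuinely open choice and Tukey is the conventional companion of one-way
ANOVA). Error bars are SEM (sample SD over sqrt(n)). `build_report`
emits per-(line, day, zone) summary tables, the per-day Welch table, the
per-line ANOVA table, and a six-panel figure; with a single day the
ANOVA is skipped with a log message rather than an error.

## Problem sizes and determinism

Validation runs use 40 spheroids per group per day for the ordering
suite and the published cohort size (83 normal / 85 cancer) for the
Day-8 classification study; maps are ~60-170 px across at the default
1 um pixel (inside the instrument's 0.5-2 um scan-step range). One seed
controls everything downstream: cohort seeds derive per-spheroid
streams, and every classification run seeds its own fold shuffle. All
thresholds, fractions and grids live in the YAML config; none are
hard-coded in the pipeline stages.

## Known limitations

* Absolute shift levels, zonal contrasts and jitter magnitudes are
  package defaults, not measured values; conclusions transfer to real
  data only at the level of orderings and of the relative benefit of
  mechanical features.
* Segmentation assumes a single spheroid per image on a darker,
  near-Gaussian background (the assay uses low seeding density); scenes
  with touching spheroids or textured background are out of scope.
* The deep-learning image classifier of the original study (DenseNet121
  on raw Brillouin images, with attribution maps) is out of scope; only
  its printed split arithmetic and F1 calculus are reproduced.
* Skewness of very small regions (tens of pixels) is noisy; the
  pipeline reports it regardless, and the validation relies on
  group-level statistics rather than per-spheroid values.
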