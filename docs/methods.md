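# Methods

`floracolor` measures plant leaf and flower colour from ordinary digital
photographs and turns it into quantities that can be compared across
species, sites and cameras: per-channel CIE L\*a\*b\* distributions, colour
differences between distributions, and proportional flower cover in
quadrats. This note records the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Colour model

All measurements are made in CIE 1976 L\*a\*b\* ("Lab"): L\* is lightness
(0–100), a\* runs green (−) to magenta (+), b\* runs blue (−) to yellow (+).
Lab is device-independent and approximately perceptually uniform for
humans, so Euclidean distance in Lab (ΔE\*ab) is a meaningful colour
difference. Inputs are assumed to be sRGB-companded rasters (TIFF/PNG/JPEG,
8 or 16 bit); sensor-native RAW decoding is out of scope — shoot RAW,
demosaic to 16-bit TIFF, then measure.

The sRGB ↔ XYZ matrix is derived in double precision from the IEC
61966-2-1 primary and D65 white chromaticities, with the reference white
taken as the image of RGB (1, 1, 1). This makes the conversion exactly
self-consistent: neutrals map to a\* = b\* = 0 to machine precision and the
round trip is exact to < 1e-9 across the gamut. Implementations built from
rounded published tables (e.g. the legacy ITU matrix in scikit-image)
differ from this one by up to ~0.015 Lab units — harmless for trait work,
but worth knowing when cross-checking. a\*/b\* are **not** clamped to
±100: genuine sRGB extremes exceed it (pure blue has b\* ≈ −107.9). The
white point is D65 (2° observer) by default; D50 is available for
cross-checks against print-oriented converters.

## Image standardisation

Camera RGB depends on the sensor and the light, so every scene includes a
24-patch ColorChecker rendition chart and each image is corrected until the
chart's six neutral patches (black, four greys, white) match their
published sRGB values. Four parameters are fitted, all acting in **linear**
RGB (gains and offsets are physical only in linear light):

* black point `β` — additive offset;
* exposure `g` — scalar gain;
* colour temperature and tint — gains `(g_R, 1, g_B)` on the red and blue
  channels (green pinned at 1), moving colours along the blue–yellow and
  magenta–green axes.

The correction per pixel is `compand(clip((linearise(v) − β) · g · g_c))`.

The original workflow did this adjustment by eye in a raw developer; this
package defines a deterministic solver instead, for reproducibility. Because
the green gain is pinned, the green channel of the neutrals obeys
`measured = expected/g + β` regardless of any colour cast, so `β` and `g`
come from a least-squares line of measured-vs-expected linear green over all
available neutrals (≥ 2 required). An alternative — black point from the
black patch alone and exposure from neutral luminances — conflates cast
gains into the offset and exposure estimates and cannot recover known
parameters exactly; the green-channel fit can, and does (relative error
< 1e-13 on noise-free synthetic charts, < 1% at pixel noise σ = 0.005).

`g_R` and `g_B` are then anchored so the grey patch whose reference
luminance is nearest the brightness of the plant part being measured
matches its reference RGB *exactly*. Sensor non-linearities make one global
balance across the whole brightness range unreliable, so the balance is
tied to the brightness that matters; "brightness" here is linear luminance
(Rec. 709 weights). Patch means are taken over the central 50% of each
patch region to avoid edge bleed. A per-patch ΔE\*ab residual report is the
quality control; ΔE < 2 on the neutrals is the package's convention for an
acceptable correction (no canonical tolerance exists). Any neutral patch at
or above the clipping threshold (default 254/255) invalidates the fit:
clipped channels carry no colour information.

## Segmentation and traits

Plant parts are isolated by per-channel thresholds in Lab (recommended),
HSB or RGB, evaluated on the **standardised** image; hue intervals may wrap.
Threshold values are user inputs recorded with the outputs — they depend on
species and background and no universal values exist. No morphological
clean-up is applied unless explicitly requested.

Each segmented specimen yields three per-channel samples. Traits are
reported as mean ± SD with skewness and kurtosis; conventions: SD uses
n−1, skewness is m₃/m₂^{3/2} and kurtosis m₄/m₂² with population central
moments — **non-excess Pearson kurtosis, normal = 3** (mind the off-by-3
against "excess" conventions). Model adequacy uses the one-sample
Kolmogorov–Smirnov statistic against the fitted model, with asymptotic
p-values. Two caveats are deliberate and documented rather than hidden:

* When parameters are estimated from the same sample the asymptotic p is
  strongly conservative (the Lilliefors effect; measured rejection rate
  < 0.02 at α = 0.05 under the null). A parametric-bootstrap p-value
  (seeded, default 999 replicates) is available as an opt-in.
* When parameters are estimated from an *independent* sample of the same
  size and the other half of the data is tested, the rate is inflated to
  ≈ 0.14 at any n, because the estimation error perturbs the hypothesised
  CDF at the same 1/√n order as the empirical fluctuation. The calibration
  that validates the machinery's size is therefore: estimate on an
  independent sample, test data genuinely drawn from the fitted model —
  measured rate 0.045–0.05 at α = 0.05 over 2,000 replicates.

Alternative 3- and 4-parameter models (skew-normal by MLE with a
method-of-moments start; beta by MLE after affine rescaling onto a declared
support) are provided to test whether the extra parameters are warranted.
The beta support for a\*/b\* is [−128, 128], not [−100, 100], so that all
gamut-valid samples lie strictly inside it; boundary samples are nudged
inward by 1e-9 with a warning. Nested fits never have lower log-likelihood
than the 2-parameter Gaussian (within optimiser tolerance).

Species-level traits are the unweighted mean of per-specimen channel means
with the SD across specimens (the "mean ± SD" trait-table shape);
pooled-pixel statistics are available as an alternative output. Fewer than
five specimens triggers a protocol warning (trait protocols recommend at
least five, preferably ten individuals).

## Colour difference

The difference between two colour *distributions* is the Earth Mover's
Distance with Euclidean ground distance in Lab: the minimum mean transport
work to morph one pixel distribution into the other. Both signatures carry
total mass 1, so the EMD is a metric in Lab units and reduces to ΔE\*ab for
two point masses. Pixel clouds are summarised as signatures by **seeded
uniform subsampling** (default K = 500) rather than histogram binning,
avoiding 3-D bin-placement artefacts; the subsampling error is bounded
empirically (< 2 Lab units against the full cloud for Gaussian clouds with
σ = 3). Binned signatures on a 16³ Lab grid are available for very large
runs.

Solver: equal-size uniform-weight signatures are an assignment problem
(an optimal extreme point of the transport polytope is a permutation) and
are solved exactly with the Hungarian algorithm; the general weighted case
solves the transportation LP (HiGHS) with one redundant marginal constraint
dropped. Both routes agree with an exhaustive rational-weight expansion
oracle to < 1e-9.

Species profiles compare each comparison specimen's signature against the
pooled signature of the target species (per-specimen averaging is available
by flag; the choice matters little for well-separated species), reporting
mean ± SD and a Student-t 95% CI over comparison specimens. Group
differences in specimen-level EMDs use Tukey's HSD (studentized range);
for two balanced groups the adjusted p equals the pooled two-sample t-test
p (q = √2·|t|), which the implementation reproduces to ~1e-14.

Distance structure is visualised by non-metric MDS minimising Kruskal
stress-1, implemented as SMACOF majorisation with monotone (isotonic)
regression of configuration distances on dissimilarity ranks (secondary
tie handling). The first start is the classical-MDS configuration, followed
by seeded random starts; best stress wins. An update that would increase
stress-1 terminates the run at the previous configuration, so the recorded
stress sequence is non-increasing by construction. Perfectly 2-D-embeddable
inputs are recovered to stress < 1e-3 and Procrustes RMSE < 1e-3 (the
classical start is already exact there).

## Cover

Quadrat photographs are rectified by a projective homography mapping the
photographed frame corners (user-supplied, ordered TL/TR/BR/BL) onto a
square with bilinear interpolation, so each pixel represents equal ground
area. Image cover is the flower-pixel fraction after thresholding. The
manual estimator treats each measured flower as an ellipse
(π · major radius · minor radius), multiplies mean area by count per
species and sums; the quadrat defaults to 10,000 cm² (1 m²). The two
estimators are compared by OLS of image cover on manual cover (R² =
squared Pearson correlation); the reverse regression is also reported since
neither variable is error-free. Image cover is expected to run lower: the
camera sees only the visible, often tilted flower face.

## Synthetic validation: what it shows and what it does not

No photographs ship with the package; every test input is generated with
known ground truth:

* **Charts**: the 24 reference patches on a grid, distorted in linear light
  by known exposure/cast gains and black offset, optional Gaussian pixel
  noise. The returned truth is the correction that exactly undoes the
  distortion. Distortions are kept below saturation — a clipped chart is an
  invalid capture by the imaging protocol itself.
* **Specimens**: foreground pixels drawn from independent per-channel
  Gaussians *in Lab* (independence is a simplification; real petals have
  correlated channels and spatial structure), converted through the exact
  inverse transform. Means must keep a 3σ box inside the sRGB gamut, so
  resampling of out-of-gamut draws stays a tail correction; strongly
  saturated colours near the gamut surface (as some real yellow flowers
  are) cannot be emulated by a symmetric Gaussian and are excluded by
  design. Default setting: a yellow flower at (60, 10, 50) with SDs
  (1.5, 1.5, 1.4) Lab units, magnitudes typical of real per-specimen flower
  colour variation.
* **Quadrats**: non-overlapping flower discs placed in disjoint cells of a
  jittered occupancy grid (placement stays O(n) even at cover 0.5, where
  rejection sampling would approach the random-packing jamming limit); the
  final disc is painted partially in row-major order so the planted pixel
  count hits the target exactly. Overlapping or senescing flowers are not
  simulated.

All generators are bit-deterministic under a fixed seed and return their
truth alongside the raster. Passing tests therefore demonstrate the
*machinery* — conversion accuracy, parameter recovery, metric correctness,
statistical calibration, cover recovery through a known homography — not
robustness to shadows, specularities, mixed illumination, chart
misdetection or off-gamut colours, none of which the generators emulate.

Validation scales (chosen as the package's standard problem sizes): 1,000
triples for round-trip checks; 5 charts per distortion regime (patch size
96 px under noise, giving the anchor-patch mean a ~7e-5 linear SE);
3,000-pixel clouds for parameter recovery; 2,000 replicates at n = 200 for
the KS size check; 11 species × 10 specimens × 2,000 pixels with K = 200
signatures (~6,000 EMDs) for the discrimination study; 20 quadrat fixtures
spanning cover 0.01–0.5 at 300 px with 10 px corner displacement; n = 400
quadrat pairs (generating slope 0.56, noise σ = 0.02) for the
method-comparison regression.

## Known limitations

* Automatic chart detection is not provided; patch regions are inputs.
* The correction model is diagonal (per-channel gains); full-matrix or
  polynomial colour correction is out of scope.
* JPEG inputs are accepted but flagged: lossy compression already discarded
  information no correction can restore.
* EMD at K = 500 costs ~0.1 s per pair; very large comparison sets should
  lower K or use binned signatures (both seeded and recorded).
* Asymptotic KS p-values inherit the Lilliefors caveat whenever model
  parameters come from the tested sample; use the bootstrap flag when that
  matters.
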