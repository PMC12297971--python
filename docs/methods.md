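# Methods

## Colour pipeline

All conversions start from 8-bit sRGB camera values, decoded with the
IEC 61966-2-1 inverse transfer function and mapped to CIE XYZ with the
standard sRGB primaries matrix on the Y = 100 scale. The adopted D65 white
point is the image of linear (1, 1, 1) under that matrix
(≈ 95.047, 100.000, 108.883). Taking the matrix's own white rather than a
separately rounded constant makes sRGB white map to L\* = 100 exactly and
every neutral input (R = G = B) land exactly on a\* = b\* = 0, which the
package treats as a definitional property of the pipeline rather than an
approximation.

HSV follows the standard hexcone model with hue in degrees and
saturation/value in percent; achromatic pixels report H = 0 so ROI
averaging stays deterministic. CIELAB uses the CIE 1976 formulas with the
linear segment below (6/29)³. The 8-bit Lab dialect
(L\* = L_s/255·100, a\* = a_s − 128, b\* = b_s − 128) is provided with its
exact inverse for compatibility with imaging libraries that store Lab in
bytes.

### CIECAM02

The forward model implements CIE 159:2004: CAT02 adaptation with a
degree-of-adaptation D, the Hunt–Pointer–Estévez cone transform, the
hyperbolic post-adaptation compression, opponent responses a and b, the
achromatic response A, and J = 100·(A/A_w)^(c·z). Numerical choices:

* **Illuminant discounting.** The camera is white-balanced to a reference
  chart before acquisition, so by default D is fixed at 1. This is also
  required for neutrality to be exact: with the exponential
  D(L_A) < 1, neutral stimuli drift off the achromatic axis. The
  exponential formula (clamped to [0, 1]) is available via
  `discount_illuminant=False`, and is used when reproducing the published
  CIECAM02 verification stimulus (J = 41.731, C = 0.1047, h = 219.048,
  matched to < 0.1).
* **Neutral snapping.** The published HPE matrix rows do not sum exactly to
  one (first row 1.00001), which would leak ~10⁻⁵ of spurious chroma onto
  neutral stimuli. Renormalising the matrix would instead shift the
  near-achromatic verification stimulus's hue by over a degree, so the
  matrices are kept verbatim and stimuli whose chromaticity equals the
  white point's are snapped to a = b = 0 by definition.
* **Default viewing conditions.** Average surround (F = 1, c = 0.69,
  N_c = 1), Y_b = 20, L_A = 4.07 cd/m² (the sRGB reference ambient). The
  acquisition environment's true values are unknown; all are configurable,
  and J at the white point is 100 under any of them.

### The two JCh dialects

`full_ciecam02` mode is CIE 159:2004 exactly: z = 1.48 + √n, the
eccentricity-weighted chroma, hue = atan2(b, a). `literal` mode is
the simplified dialect applied pipelines tend to use: z = 1.48 + n,
C = √(a² + b²), and — crucially — the hue arctangent taken with the
opposite axis ratio, quadrant-correct atan2(a, b), i.e. 90° − h for
first-quadrant colours.

The axis order in the literal dialect is a deliberate design decision, not
a typo. The pressure-response feature set is characterised by a fixed sign
structure: when redness weakens, the JCh hue **falls** while the HSV hue
**rises**, and the two hues correlate at r ≈ −0.98 while JCh hue and a\*
correlate at r ≈ +0.78. A standard atan2(b, a) hue co-rotates with the HSV
hue for skin tones — an exhaustive search over realistic RGB shifts finds
no displacement that lowers it while raising H — so only the axis-swapped
reading reproduces that empirical sign structure. The image pipeline
defaults to the literal dialect for this reason; the full model remains the
default everywhere conversions are used on their own.

## Imaging

Frames are single TIFFs per time point, sorted lexicographically, with
acquisition time assigned as index/fps. Tilt from body movement is
corrected by rotating about the midpoint of the wrist–elbow segment until
the segment is horizontal (bilinear interpolation, zero fill, landmark
order normalised so the result is invariant to swapping wrist and elbow).
ROI cropping is strict — a box that leaves the frame is an error, never
clamped. Components are averaged **per pixel** (each pixel converted, then
means taken), matching the component-mean definitions; converting the mean
RGB instead is available as `mean_first` and differs for the nonlinear
spaces. Hue is averaged arithmetically by default — skin hues sit tens of
degrees from the 0/360 wrap, so the circular and arithmetic means agree to
well under 0.1° there — with a circular option for unusual colour ranges.

## Feature table and standardization

Class 0 is the baseline-midpoint frame (t = 5 s by default); class 1 is the
first frame at least 1 s after cuff release, inside the residual-blanch
window before hyperaemia. Exactly two rows per subject. Standardization is
a pooled per-column z-score (SD with n−1), stored for inversion and
idempotent; the leakage-free alternative that refits scaling inside each CV
training fold is available (`scale_within_fold`) and changes results only
marginally at these sample sizes.

## Classification

The classifier is bagging over CART trees: Gini splits, maximum depth 38,
no other pruning, minimum leaf 1, 31 bootstrap resamples of size n drawn
with replacement. Scores are the across-tree mean leaf probability of
class 1 (a vote-fraction rule is available). Evaluation is stratified
5-fold cross-validation with folds shuffled by seed; every sample receives
exactly one out-of-fold score and the pooled scores feed a single ROC
(per-fold AUCs are logged as a diagnostic). AUC uses the trapezoid over all
distinct thresholds, which with the half-credit tie convention equals the
pairwise-concordance estimator.

**Grouped folds.** With paired data (two samples per subject carrying
opposite labels) plain stratification can split a pair across folds. A
depth-38 tree then memorises the twin — nearly identical coordinates,
opposite label — and systematically *anti*-predicts the held-out sample:
on null data this drives the pooled AUC far below 0.5 (≈ 0.09 observed on
the image fixture) instead of to it. Cross-validation therefore keeps each
subject's pair in one fold (stratified group k-fold) whenever subject IDs
are available; fold sizes and class balance (8 samples, 4 per class at
n = 20 subjects) are unchanged.

Threshold metrics (precision, recall, F1 = their harmonic mean) are
reported at score ≥ 0.5, with precision defined as 0 plus a warning flag
when nothing is predicted positive. AUC values are labelled with the usual
seven interpretation bands (ideal / very good ≥ 0.9 / good ≥ 0.8 /
acceptable ≥ 0.7 / low > 0.5 / random = 0.5 / worse than random).

## Statistics

Per component, both class samples get Shapiro–Wilk W and p; the class
comparison is a paired two-sample t-test on the standardized values
(t = mean(Δ)/(SD(Δ)/√n), Δ = class 0 − class 1, df = n − 1, two-sided p)
and the paired Cohen's d in the d_z form, mean(Δ)/SD(Δ) = t/√n exactly.
d_z is the primary effect size because the observed d ≈ t/√n
cross-consistency singles it out; the pooled-SD variant is behind a flag.
Redundancy: pairwise Pearson matrix (constant columns are an error), PCA as
the eigendecomposition of the correlation matrix (matching standardized
features; ratios sum to 1), and permutation importance — each feature
column shuffled `n_repeats = 30` times (seeded), importance = baseline
metric − permuted metric, evaluated out-of-fold via the grouped CV splits
so that redundant features honestly score near zero.

## Synthetic data

**Feature level.** Per subject i and component vector:
x₀ᵢ = μ + SD·(sᵢ + e₀ᵢ), x₁ᵢ = μ − d·SD + SD·(sᵢ + e₁ᵢ), with the shared
subject effect s ~ N(0, ρΣ) and residuals e ~ N(0, (1−ρ)Σ) all drawing the
same correlation matrix Σ, so the within-class covariance is exactly Σ for
any ρ. The subject-effect share defaults to **ρ = 0.5**: at that value
SD(Δ) = SD·√(2(1−ρ)) = SD, so the configured effect size d is
simultaneously the marginal standardized class separation and the
population paired d_z — the only ρ for which both calibration properties
hold at once. Default effect sizes are d = 2.28 (h), 2.29 (a\*), −2.29 (H)
and the default Σ carries r(H, a\*) = −0.78, r(H, h) = −0.98,
r(a\*, h) = 0.78; mildly non-PSD user matrices are repaired by eigenvalue
clipping with a warning, grossly non-PSD ones rejected. Default n = 20 per
class matches the cohort size. Component means and SDs default to typical
light-intermediate (Fitzpatrick II–III) skin values; they only set the raw
scale and cancel under standardization.

**Image level.** Frames follow a phenomenological perfusion trace: stable
baseline; linear blanch ramp over the 30 s compression; full residual
blanch for `settle_s = 2 s` after release (so the class-1 frame at +1 s is
residually blanched, matching the directional findings); then the blanch
decays (τ = 3 s) while a hyperaemic overshoot rises and decays
(amplitude 0.6, τ = 10 s). The default blanch displacement (+0, +12, +6 in
R, G, B) encodes reduced haemoglobin absorption — more green and blue
light — which lowers a\* and the literal JCh hue and raises the HSV hue;
the hyperaemia displacement is redder. Static per-pixel texture
(SD 2.5) is seeded once per subject; sensor noise (SD 1.5) is redrawn per
frame; pixels clip to [0, 255] with the clipped fraction logged (< 1% at
defaults). Subject diversity comes from seeded jitter of the baseline tone
(SD ≈ 4, 3, 3). The generator is *not* a haemodynamic model: it encodes
the direction and timing of the colour change, not chromophore optics,
motion artefacts or illumination drift — so passing end-to-end tests shows
the pipeline recovers planted colour dynamics, not that it handles real
acquisition artefacts.

## Problem sizes and determinism

End-to-end image tests use 20 subjects at reduced frame geometry
(60 × 80 px, 50 × 50 ROI, 3 fps) — the dynamics, protocol timing and
analysis path are identical to the full-resolution defaults, and the ROI
mean is insensitive to resolution beyond noise averaging. The replicated
small-sample classification runs use 50 replicate datasets; the
Monte-Carlo standard error of the mean AUC is then ≈ 0.008, and the
acceptance test allows 2.33 such standard errors so that it fails only if
the population mean is genuinely below target. Every stochastic step —
generators, fold shuffling, bagging bootstraps, permutation shuffles — is
seeded, and identical configurations reproduce bit-identical tables and
reports.

## Known limitations

* The CIECAM02 viewing parameters of the original acquisition environment
  are unknown; JCh magnitudes (not signs) depend on them.
* The literal-dialect hue axis is inferred from the empirical sign
  structure of the feature set, as discussed above; pipelines using the
  standard atan2(b, a) hue will see the JCh hue co-rotate with HSV hue.
* The three-component model's performance collapse on real recordings is a
  data-specific multicollinearity phenomenon; the synthetic generators do
  not attempt to reproduce it, only to support running that model.
* Real between-subject variance of the 12 components is unavailable;
  generator defaults reproduce the directional and effect-size structure,
  not empirical population spreads.
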