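# Methods

`spermshape` quantifies sperm-head morphology from traced outlines. This
note documents the model, the conventions the implementation commits to,
the synthetic data generator, and the numerical choices that a user of
the results should know about.

## Outline model: elliptic Fourier descriptors

A closed head contour, parameterized by cumulative arc length `t` over
perimeter `T`, is expanded as

    X(t) = A0 + Σ_n [ a_n cos(2πnt/T) + b_n sin(2πnt/T) ]
    Y(t) = C0 + Σ_n [ c_n cos(2πnt/T) + d_n sin(2πnt/T) ],   n = 1..N.

Coefficients are estimated with the classical closed-form line-integral
estimator for piecewise-linear contours (the chain-code formulation of
outline morphometrics). The default harmonic order is `N = 20`, high
enough that reconstruction error is below 1% of the perimeter for
smooth head shapes; it is configurable everywhere.

**Normalization.** The starting-point phase and the rotation of the
first-harmonic ellipse are removed and its semi-major magnitude divided
out, leaving `a1 = 1`, `b1 = c1 = 0`. The surviving first-harmonic
coefficient `d1 ∈ (0, 1]` (for counter-clockwise contours) is the
first-harmonic aspect ratio — the "thinness" indicator the analysis is
built around. The removed scale, rotation and phase are recorded so
absolute axis lengths can be restored. The free-parameter vector
`(d1, a2, b2, c2, d2, …, dN)` has length `4N − 3` (77 at `N = 20`).

**A residual 180° ambiguity** remains after phase/rotation removal: the
two solutions differ by flipping the sign of every even-harmonic
coefficient. The implementation picks the variant in which the
dominant (largest-magnitude) even-harmonic coefficient is positive,
anchoring the orientation to the shape's own asymmetry; exactly
symmetric outlines (where all even harmonics vanish, e.g. ellipses) tie,
and the smaller starting-point phase wins. This rule is stable for
falcate heads, whose even-harmonic content is far from zero, whereas
rules based on the reconstructed tip position sit within numerical
jitter of the decision boundary for this shape family.

**The first harmonic is a Fourier construct, not a geometric fit.** For
an eccentric geometric ellipse traversed at constant speed, the
coordinate signals are not single harmonics: a 2:1 ellipse has
first-harmonic axis ratio 0.58686, not 0.5, and in the flat limit the
signal degenerates to a triangle wave (first-harmonic amplitude 8/π² of
the geometric semi-axis). Consequently `d1` is a monotone, slightly
compressed proxy of the geometric axis ratio. All planted effects in the
synthetic generator and all recovered quantities live consistently on
the `d1` scale, so group contrasts are unaffected; users comparing `d1`
against caliper-style geometric measurements should expect the offset.

## Segmentation and tracing

Images are binarized with Otsu's discriminant criterion, implemented as
an exhaustive scan of the 256 grey levels for the maximum between-class
variance; ties break toward the lowest level, and foreground is the
bright class (`grey ≥ threshold`), matching stained nuclei on a dark
background. Connected components are 8-connected; components smaller
than `min_area` (default 200 px²) are treated as debris. The outer
boundary of each component is Moore-neighbor traced into a Freeman
chain code. The geometric frame is fixed once: image row `r` maps to
`y = −r` (y-up, origin at the top-left pixel center), and every emitted
chain is counter-clockwise (positive shoelace area), which keeps `d1`
positive downstream. Holes and touching-object splitting are out of
scope.

The `.chc` dialect is one record per line —
`specimen_id start_x start_y code1 … codeK` — with `#` comments, LF
endings on write, and a permissive reader (blank lines, CRLF). Chains
must be closed; duplicate ids are deterministically suffixed.

## PCA, loadings, and the abnormality filter

PCA is performed on the covariance matrix (divisor `n − 1`) of the
flattened coefficient vectors — coefficients share a dimensionless
scale, so no correlation rescaling is applied. Contribution rates are
eigenvalue fractions of total variance; zero eigenvalues are retained.
Sign conventions are fixed so results are reproducible across runs:
PC1 is oriented with a non-negative `d1` eigenvector entry (higher PC1 =
rounder, so shape outliers that lack the hook land at high positive
scores), and every other PC has its largest-magnitude entry positive.

Factor loadings are correlations between original coefficients and PC
scores (`e_jk √λ_k / s_j`); biplot arrows combine the PC1/PC2 loadings
and arrows longer than 0.1 are flagged for display.

The abnormality filter is two-pass: PCA on all specimens anchors the
score scale; specimens with pass-1 PC1 score above the threshold
(default 0.55) are excluded as abnormal; PCA is refit on the remainder.
The threshold applies to pass-1 scores with abnormal specimens included,
because their admixture is precisely what stretches PC1 toward the
abnormal cluster. Hook presence is not a second computational gate; the
score threshold alone decides.

## Head measurements

From the normalized first harmonic: `major = 2·scale_px`,
`minor = major·d1`, `aspect_ratio = d1`. From the traced contour: the
antero-posterior (AP) axis is the longest chord over contour vertices
(evaluated on the convex hull, which attains the same maximum as the
full O(V²) scan); `θ` is the acute angle between the AP chord and the
first-harmonic major axis, in degrees in [0, 90); head area is the
absolute shoelace area of the boundary polygon. Lengths are in pixels
with an optional µm-per-px factor in the pipeline configuration.
Population dispersion is the coefficient of variation,
`100·SD(n−1)/mean`.

## Group statistics

Classic tests wrap scipy: two-sample t (pooled variance by default,
because the F variance-ratio test accompanies it; Welch by flag),
one-sample t, the F test, the two-sample Kolmogorov–Smirnov test, and
Shapiro–Wilk. The KS p-value uses the plain Kolmogorov asymptotic tail
of `sqrt(nm/(n+m))·D` without small-sample corrections — the convention
of R's `ks.test(exact = FALSE)` — computed from the exact alternating
series. Labels follow `p > 0.05` n.s., `< 0.05` \*, `< 0.01` \*\*,
`< 0.001` \*\*\*.

Steel–Dwass is implemented from scratch: for every pair of the `k ≥ 3`
groups, joint mid-ranks give a Wilcoxon rank-sum statistic standardized
with tie correction, and `p = P(Q_{k,∞} ≥ √2·|z|)` under the studentized
range distribution. This is the large-sample single-step max-T
approximation (no continuity correction); its family-wise type-I error
at α = 0.05 stays below 0.07 in null simulations with k = 4, n = 20.
Percent difference is `100·(reference − test)/reference`, with the
reference group named explicitly in every report because the sign
semantics ("thinner than") depend on it.

## Synthetic populations

The generator produces study-shaped data with exact ground truth. Its
defaults are the study conditions: mean `d1` 0.5, coefficient of
variation 5.3% (cauda-epididymal scale; 8.4% and 6.0% for
caput/corpus-like populations), hook curvature 0.15 on a [0, 0.3]
scale, fore-aft taper 0.10, and 10% abnormal admixture where a filter
is being exercised.

**Templates** are geometric: an ellipse, a taper shear, and a
circular-arc bend producing the falcate profile. Shears and moderate
bends are injective plane maps, so templates are simple by
construction. Because of the first-harmonic compression described
above, the base axis ratio is root-solved so the *measured* `d1` of the
finished template equals the requested aspect exactly (≈1e-12).

**Population variation** is planted in normalized coefficient space
around the template's vector, as four components:

- a width mode — per-specimen `d1` drawn from a truncated normal
  (mean × CV), with the planted entry root-solved so the measured `d1`
  equals the draw exactly;
- a hook-curvature mode and a taper mode — directions measured from the
  geometric family, amplitudes in the proportions 19.3 : 12.7 relative
  to 49.8 for the width mode (the contribution-rate structure reported
  for real cauda sperm);
- a ripple mode along the direction in which the *other* coefficients
  co-vary with width (an arc-length reparameterization effect), at 3.0
  population SDs of that coupled drift, plus isotropic per-coefficient
  jitter (SD 0.006). Without this width-independent variation every
  coupled coefficient would track `d1` deterministically — real outline
  data carry substantial independent variation per coefficient, and the
  dominance of the `d1` loading on PC1 depends on it.

Planted modes pass through the synthesis map (truncated series →
contour → re-estimation), which attenuates them; each mode's
directional gain is probed at its working amplitude and pre-compensated.
Specimens that self-intersect after jitter are redrawn with shrinking
amplitude. Every contour receives a random rigid rotation, translation,
and size (CV 8% around `scale_px`).

**Abnormal specimens** emulate hook-lacking, rounder heads with
irregular margins: a base ellipse (axis ratio 0.76, keeping the
normalization frame stable) carrying fixed-phase 6- and 7-fold lobes
(amplitudes 0.52/0.43 with 4% jitter). The recipe places the class
roughly 0.76 away from the normal cluster in coefficient space along a
consistent direction, so pass-1 PC1 separates it cleanly above the 0.55
score gate — the defining property of the class. Their recorded
`true_aspect` is the measured `d1` (≈0.8).

**What the generator does not emulate:** optical texture, debris,
touching cells, acrosomes and tails, tracing noise correlated along the
boundary, and any biologically realistic covariance between head size
and shape (size is independent of the planted modes). Passing the
recovery tests therefore demonstrates that the *pipeline* is unbiased
and well-calibrated under the assumed statistical structure, not that
the structure matches any particular real dataset.

**Rendering** fills the polygon with a robust inside-or-on pixel-center
rule, then applies optional Gaussian blur (PSF SD in pixels) and
additive Gaussian noise clipped to [0, 255]. Round-tripping a rendered
head of semi-major ≈100 px through segmentation and EFD reproduces `d1`
within 0.01.

## Problem sizes and determinism

Everything is deterministic given seeds: populations hash identically
across runs, and pipeline reruns produce byte-identical CSVs. The
planted-effect studies use two groups of 150 specimens averaged over 10
seeds (strain scale), 118/133 (zona scale), and 69/85/118 with CVs
8.4/6.0/5.3% (maturation scale) — the reported group sizes of the
source study — which keeps a full run of the test suite and the
acceptance script within a few minutes on one core.

## Known limitations

- `d1` is the first-harmonic aspect ratio, not the geometric axis
  ratio; the two differ systematically for eccentric outlines (0.587
  vs 0.5 at 2:1).
- Re-measuring a contour synthesized from a coefficient vector does not
  return the vector exactly (arc-length reparameterization); the
  generator compensates where ground truth demands exactness, and PC
  reconstruction tests account for the bias (≲1e-4 near the mean shape,
  a few percent at ±2 SD displacements).
- The Steel–Dwass p-values are asymptotic; at group sizes below ~8 with
  heavy ties they can deviate from the permutation null by a few
  hundredths.
- The Moore tracer ignores holes and cannot split touching objects.
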