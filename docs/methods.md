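# Methods

This note documents the models, conventions and parameter choices behind
`wormquant`, in the order the pipeline runs them, and states what the
synthetic tests do and do not establish about real data.

## Imaging model and segmentation

**Acquisition geometry.** One animal = four body-region z-stacks, 30 slices
at 3 µm spacing, 512×512 px at 0.4 µm/px, two channels per slice (green:
reporter + autofluorescence; red: autofluorescence only).  Regions are
treated as spatially disjoint; nuclei are never matched across regions, so a
nucleus straddling a region border could in principle be counted twice.  All
coordinates are 0-based `(slice, row, col)`; centroids are float pixels.
Intensity units are arbitrary (camera gain and bit depth are not modelled).

**Canonical stage order.** Per region: (1) subtract red from green slice-wise
and clip negatives to zero; (2) threshold each slice of the difference
independently with an automatic histogram method (Otsu's bimodal-separation
criterion by default; "triangle" and fixed numeric thresholds are available;
the value used is logged per slice, and a contrast-free slice yields an empty
mask with a warning, not an error); (3) binary opening with a disc of radius
1 px (configurable; radius 0 is the identity; out-of-image pixels count as
background for both erosion and dilation, so opening never adds pixels);
(4) 8-connected in-plane labelling — components are 2-D per slice because
deduplication, not 3-D labelling, handles the axial extent; (5) shape
filtering with the printed inequalities taken literally: extent ≥ 0.50
(inclusive), eccentricity < 0.85 (strict), solidity > 0.75 (strict);
(6) size filtering with inclusive bounds, defaults 4–120 µm² converted
through the pixel size (25–750 px at 0.4 µm/px) — calibration parameters
whose meaning is fixed ("smaller than neurons, larger than intestinal
nuclei") but whose values depend on optics; (7) across-slice deduplication.

An alternative order — binarise each channel first and subtract the masks
(`binary_subtract=True`) — is provided for compatibility.  It requires every
slice of each channel to threshold cleanly on its own: on a noise-only red
slice an automatic threshold splits the background and the subtraction then
punches pseudo-random holes in the nuclei.  The intensity-subtraction order
is therefore canonical and the compatibility mode is only exercised on
noise-free scenes.

In `segment_region` the size bounds are applied to the labelled mask before
feature extraction (the `bwareaopen` idiom).  The shape and size filters are
independent per-object predicates, so this commutes with filtering after
feature extraction; it only avoids computing convex hulls for thousands of
noise specks.

**Features.** Area, centroid, bounding-box extent, eccentricity (from the
second central moments / inertia-tensor eigenvalues) and equivalent diameter
`√(4A/π)` follow the standard regionprops definitions.  **Solidity** uses an
explicit exact convention: the convex image is the set of pixel centres
inside (boundary inclusive) the convex hull of the object's own pixel
centres.  Under this convention a digital disc has solidity exactly 1 and
every concavity strictly lowers it; because hull vertices are integer lattice
points, the boundary-inclusion decision is exact, which lets an independent
integer-arithmetic implementation (monotone chain + orientation tests, in the
test suite) reproduce the value bit-for-bit.  Per-nucleus total intensity is
summed over the *subtracted* stack, not the raw green channel — summing raw
green would re-admit the autofluorescence the subtraction removed.

**Deduplication.** "Within ±4 px" is read as a per-coordinate (Chebyshev)
box, applied to all slice pairs within one region with transitive closure,
not only adjacent slices.  Each group keeps its largest-area member; area
ties keep the lowest slice index, then the lexicographically smallest
centroid (deterministic and logged).  Note that the post-dedup nucleus count
is *not* strictly monotone under filter tightening: removing a mid-chain
object can split one group into two.  The guaranteed monotonicity (tightening
a filter never admits more objects) holds at the filter stage and is tested
there; end-to-end monotonicity is checked empirically on default scenes.

## Tissue classifier

A CART-style binary tree ("fine tree": a high split budget, default 100)
with Gini impurity, candidate thresholds at midpoints between consecutive
sorted unique feature values, grown best-first by total impurity decrease.
Ties are broken by lowest feature index, then lowest threshold, then node
creation order, making training invariant to input permutation; a
single-class input returns a depth-0 majority tree with a warning.  Features
are area, eccentricity and equivalent diameter; the latter is a deterministic
function of area, which the tree tolerates (it simply never gains from the
redundant split).  No pruning, cost weights or cross-validation — the study
design is a single 600-train / 200-validation split, which the pipeline
mirrors.  "Normalised total intensity" per tissue is implemented as division
by the same tissue's ad-libitum control total (fold change), with a per-worm
fraction mode as the selectable alternative, since the normalisation is
otherwise underdetermined.

## Nucleolus scoring

Manual counting is replaced by a ratio rule: centre disc = pixels of the
*image* within radius `0.3 × equivalent_diameter / 2` of the centroid (the
disc is taken on the image, not intersected with the mask, because an empty
nucleolus has no mask pixels at its centre); ring = mask pixels outside the
disc.  Call = filled iff centre-mean / ring-mean ≥ τ (default 0.6); empty
below; indeterminate when the disc contains no pixel centre or the ring is
empty/zero.  The rule is scale-invariant and monotone in τ.  τ and the
centre fraction are calibration parameters validated only on synthetic
ground truth; real nucleoli vary in size and position, so these defaults
should be re-calibrated before use on microscope data.  Scoring is applied to
intestinal nuclei only.

## Survival analysis

Kaplan–Meier product-limit curves are fitted with `lifelines`; deaths precede
censorings at tied times.  "Mean lifespan" is the restricted mean survival
time up to the last observed death, integrated directly from the step
function (a plain running product over the event table), so that with no
censoring it telescopes to the arithmetic mean of death times to float
rounding; the lifelines RMST utility is the independent cross-check in the
tests.  Mortality quantile q = the smallest observed death time with
S(t) ≤ 1−q; a curve that never reaches the level returns `None` with a
warning.  Deaths scored "every 3rd day" are treated as exact at the
observation day, matching scoring practice; the cohort simulator can snap to
the 3-day grid, but its default keeps exact times so that noise-free runs are
exactly linear.

## Dietary-restriction regimes and food availability

The regime grid is 3 concentrations (10⁹, 10⁸, 0 OP50 cells/ml) × 3 exposure
times (6, 12, 24 h) applied on adult days 1, 4, 7, 10, plus an ad libitum
control (10¹⁰ cells/ml, 0 h).  Food availability integrates the
piecewise-constant concentration profile from the start of adult Day 1 to
Day 11 (end of the last exposure): ad libitum everywhere except the exposure
windows, which start at 00:00 of each exposure day (clock time is not
specified by the assay; this is a convention).  Closed forms: control
10¹⁰ × 10 = 10¹¹; (10⁸, 12 h) → 8.02×10¹⁰; (0, 24 h) → 6.0×10¹⁰ cells·day/ml.

## Association analysis

Regressions are at the **regime level** — one point per regime (9 DR +
control, control included by default), response = KM mean lifespan,
predictor = the regime's mean cumulative intensity or food availability,
unweighted OLS with intercept.  Predictors are standardised internally and
the coefficients mapped back to the raw scale (cells·day/ml magnitudes of
10¹¹ would otherwise make the quadratic design numerically singular);
coefficient covariances are transformed alongside.  A constant response
yields R² = 0 with a degenerate flag rather than a 0/0.  Quadratic fits
report the vertex −c₁/(2c₂).  One-way ANOVA + Tukey HSD is included as a thin
reporting utility only.

## Synthetic data: what it emulates, and what it does not

**Scenes.** Nuclei are anisotropic Gaussians truncated to ellipsoidal
supports — profile `A·exp(−0.35·r²)` with r = 1 at the support edge, so edges
sit at ~0.70 of peak and thresholding has a genuine boundary to get wrong —
spanning 1–4 consecutive slices with the largest cross-section and intensity
on the central slice.  Tissue identity sets the size/eccentricity priors
(area gaps between classes at overlap 0; a configurable overlap makes classes
genuinely ambiguous).  Intestinal nuclei are rendered hollow (a dark
nucleolar core, ~0.1 of peak at the centre) with probability
`hollow_fraction`.  Blobs are unions of 2–4 overlapping discs planted at
*identical* intensity in both channels.  Background is additive Gaussian
(mean 100, sd 12 per channel); with nucleus peak amplitudes of 70–120 a.u.
the peak SNR against the subtracted image's √2-inflated noise is ≈ 4–7,
emulating a dim single-copy reporter.  Placement is rejection sampling with
non-overlap enforced via bounding boxes; failure to place within the attempt
budget raises a `PlacementError` rather than silently dropping objects.
Ground truth records, per nucleus, the 3-D rendered intensity (for exact
conservation checks against the noiseless stack) and the central-slice sum —
the latter is the measurement target, because the pipeline's dedup rule
reports the single largest-slice object.

Not emulated: optics (no PSF, no axial blur beyond the slice-scaling),
anatomy (no worm body, embryos or edges), photobleaching, and absolute
intensity units.  Passing the recovery tests therefore shows the algorithm is
correct and well-calibrated *for this class of scene statistics*, not that
the default thresholds are right for any particular microscope.

**Cohorts.** Expected total nuclear intensity is
`baseline + A · g_conc(log₁₀ c) · g_time(h) · atten(day)` with Gaussian bumps
centred on 10⁸ cells/ml (σ = 1 decade, with a 10⁶ pseudo-count so starvation
is defined) and 12 h (σ = 8 h), and attenuation 1.0 / 0.70 / 0.35 / 0.03 on
days 1/4/7/10 — the Day-10 increment (~24 a.u.) is statistically
indistinguishable from control at imaging sample sizes, reproducing the loss
of responsiveness after the reproductive period.  Zero exposure returns the
baseline (200 a.u. — liquid-culture controls show mild nuclear localisation,
hence a positive baseline).  Per-animal per-day intensities add Gaussian
noise (sd 60 a.u.); lifespan = 14 d + 0.003 d/a.u. × cumulative intensity +
1.5 d × z, where z is a standardised Weibull(shape 4) deviate — worm-like
mortality curvature that degenerates to exact linearity in the noise-free
limit (control ≈ 16.4 d, best regime ≈ 22 d, a ~35 % extension).  The family
is pluggable in principle; only Weibull is implemented.  Censoring models
independent handling loss: with probability 0.05 an animal receives a
Uniform(3, 25) d loss time and is censored if it precedes death — independent
censoring, so KM stays unbiased.  `calibrate_lifespan_noise` inverts the
regime-level R² formula `R² ≈ b²Var(x̄)/(b²Var(x̄) + σ²/n)` to target a
population R² for the replicate-distribution checks.

## Numerical conventions and degenerate inputs

- Rendering and subtraction in float64; stacks written to disk as 16-bit
  TIFF (rounded, clipped) — lossless for uint16 data.
- All randomness flows through `numpy.random.Generator` seeded from explicit
  seed sequences; pipeline stage seeds are spawned from the run seed, and
  identical configs produce byte-identical CSV/JSON outputs.
- Restricted-mean and aggregation sums are plain sequential float sums;
  "exact" identities hold to ~1e-12 relative (float reassociation).
- Empty classes in tissue aggregation are flagged (`per_cell_defined=False`)
  instead of propagating NaN; empty validation sets, all-censored curves,
  constant predictors and rank-deficient quadratic designs raise or flag
  as documented above.

## Problem sizes in the shipped tests and drivers

Unit tests use 64–128 px stacks with handfuls of objects; the recovery
acceptance test renders 20 animals (80 full 30×512×512 stack pairs); the
exhaustive-reference equivalence runs 50 randomised 8×64×64 stacks; the
replicate-distribution check uses 200 cohort replicates at 50 animals per
regime; the analysis drivers use 6–12 imaged worms and 200 animals per regime
for the lifespan arm, mirroring the imbalance of imaging versus lifespan-assay
throughput in this kind of study.

## Known limitations

- Thresholding is per-slice and global; very dense scenes or strong intensity
  gradients within a slice would bias it.  The automatic method is selectable
  and logged so that a fixed calibrated value can be substituted.
- The dedup rule keeps a single slice's object per nucleus, so the intensity
  readout is a central-section proxy, not a volume integral; the synthetic
  ground truth mirrors this convention.
- The nucleolus ratio rule is validated only against the synthetic hollow
  model; the 0.6 threshold is not a biological constant.
- The classifier sees measured shape features; systematic segmentation bias
  (e.g. threshold truncation shrinking areas) shifts the effective class
  boundaries relative to the planted priors.
- Regime-level regression treats each regime's mean as one observation;
  per-animal regression is available (`linear_fit` on the cohort table) but
  conflates within- and between-regime variance and is off by default.
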