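# Methods

`stenoselect` implements a wrapper feature-selection pipeline for binary
coronary-stenosis classification from 64×64 grayscale angiogram patches:
a feature bank (intensity, GLCM texture, vessel morphology under eight
enhancement filters), a scalarized two-objective wrapper fitness evaluated
with an SVM, and a diversity-controlled hybrid metaheuristic combining a
Boltzmann univariate marginal distribution algorithm (BUMDA) with simulated
annealing (SA).

## The optimization problem

A candidate solution is a bit vector `x ∈ {0,1}^n` marking selected
features.  Its fitness is

```
F(x) = w_acc · Acc_val(x) + w_fdr · FDR(x),      w_acc = 0.90, w_fdr = 0.10
FDR(x) = 1 − |x| / n
```

where `Acc_val` is the holdout (validation-split) accuracy of a linear SVM
trained on the training split restricted to the selected columns, and FDR is
the feature decreasing rate (the feature-reduction objective — not the false
discovery rate).  Final reporting additionally uses the Jaccard variant
`Jc = (TP+TN) / ((A+P) − (TP+TN))`, F1, sensitivity and specificity; with
`A = P = N` the Jaccard variant satisfies `Jc = Acc / (2 − Acc)`, which the
tests verify against all comparison-table values.

Empty masks are invalid; the evaluator raises and the optimizer assigns
fitness 0.  Degenerate metric denominators raise rather than silently
returning 0, so misuse inside the optimizer loop is loud.

## BUMDA over bit vectors

From the selected fraction of the population the algorithm builds a
per-feature marginal model using Boltzmann weights
`W(X_j) = g(X_j)/Σ g`, mean `μ_i = Σ_j W(X_j) x_ij` and variance
`ν_i = Σ_j W′(X_j)(x_ij − μ_i)²` where `W′` carries a `+1` in its
denominator (so `Σ W′ = G/(G+1)`, checked to 1e−12 in tests).  The original
algorithm is a continuous-domain EDA; here each bit of a new individual is
drawn independently as Bernoulli(μ_i).  μ is clamped to
`[1/n, 1 − 1/n]` so no feature ever fixates — premature fixation is the very
failure mode the diversity control targets — and ν is retained as a
convergence diagnostic.  `g` is the raw fitness in [0,1] by default; an
`exp(β·fitness)` weighting is available via `RunConfig.boltzmann_beta`.

A truncation threshold θ advances from the sorted fitness vector
(worst-member fitness at generation 1, then the half-point fitness whenever
it clears the previous θ) and never decreases.  In the plain BUMDA baseline
θ acts as a floor on model membership with the selection rate (0.80) as a
cap.  In the hybrid driver θ is tracked as a diagnostic only: because it is
non-decreasing over the whole run, using it as a gate would immediately
filter a deliberately diversified (worst-first) population back down to its
top members and neutralize the diversity control; model membership there is
the leading `⌈0.8·npop⌉` members of the sorted population, whichever way the
sort is oriented.

## SA refinement

The neighborhood move flips each bit with probability `1/n` (at least one
flip forced; the result is repaired to keep one set bit), giving an expected
Hamming step of `1 + (1−1/n)^n ≈ 1.37`.  Improving moves are always
accepted; worsening moves with the Metropolis probability `exp(ΔE/T)`.  The
temperature falls linearly from 1 to 0 (full-scale step 0.001, ≈1000
iterations).  The refiner returns the best-so-far individual, so refinement
never worsens its input.  Inside the generation loop each refinement spends
a shortened schedule (`sa_iters_per_refinement`, default 50 iterations, the
same 1→0 temperature ramp with a proportionally larger step); the full
schedule per refinement is available by setting the knob to `None`.

## The diversity-controlled hybrid loop

Per generation: evaluate all individuals; SA-refine the current best *and*
the current worst member (refined individuals replace their originals);
update the global best only on strictly greater fitness (the global best is
reported, never re-injected); then sort the population **worst-first iff the
refined worst now outranks the refined best**, else best-first; build the
marginal model from the leading selection-rate fraction of the sorted
population; sample the next generation.  Ties in sorting keep the original
population order.

Worst-first generations model the next population on low-fitness
individuals.  The effect, at full scale, is that selection frequencies stay
closer to uniform (wider exploration) and the best result arrives in later
generations.  Two properties of the mechanism matter for reproducing it at
reduced scale:

* The trigger compares two best-so-far SA chains started from the two
  population extremes.  It fires at a useful rate only while the population
  has not collapsed onto a fitness plateau — exactly the regime of the
  full-scale problem, where the feature count (hundreds) is comparable to
  the number of training rows, SVM overfitting makes large masks genuinely
  bad, and SA refinement is transformative from any start.
* The paired diversity-trend checks therefore use an overfitting-prone
  testbed (40 training rows, 30 features, class shift 1.0, validation 60,
  test 40) rather than an easy one where validation accuracy saturates for
  most masks and the trigger almost never fires.

Baselines sharing the logging contract: an elitist generational GA
(tournament parents from the best 0.8 fraction, one-point crossover,
per-bit mutation 1/n), plain SA over the shared schedule, plain BUMDA
(no refinement, no diversity), and the hybrid without diversity.

## Classifier contract

In-loop fitness uses a linear SVM (deterministic primal solve, C = 1 fixed —
the regularization is deliberately not tuned so the fitness landscape stays
stable across subsets).  After selection finishes, a fine-tuned polynomial
kernel `(⟨x,x′⟩/scale + offset)^order` with order 5, scale 2, offset 0.3569
is available for final evaluation.  Features are standardized to zero mean
and unit variance using training-split statistics only; filter-response
features span orders of magnitude, and SVM kernels need comparable scales.
Predictions threshold the decision function at 0 (predict positive iff
score ≥ 0).

## Feature bank

Per patch (vessels darker than background, the X-ray convention):

* **Intensity** (6): min, max, median, mean, variance, std of raw pixels.
* **Texture** (14): Haralick statistics of a symmetric, normalized GLCM.
  Defaults: 8 gray levels by linear binning of the observed range, unit
  offsets {(0,1),(1,0),(1,1),(1,−1)}, matrices averaged over offsets.  The
  information-measure and maximal-correlation statistics guard degenerate
  (single-gray-level) inputs by returning 0 with a warning.
* **Per enhancement method** (8 methods × 35): the six intensity statistics
  of the response plus 29 morphology descriptors of its Otsu segmentation.

The eight enhancement methods and parameters: Frangi vesselness and a
Salem-style Hessian-eigenvalue vesselness variant (Sato formulation) over
σ ∈ [1, 12] step 0.5; single-scale Gabor (45 orientations over 180°, vessel
thickness T = 5 px, kernel elongation 2.5) and multi-scale Gabor (3 scales,
T ∈ [2, 20], 45 orientations); a multi-scale linear matched filter
(zero-mean 1-px line kernels, lengths 1–15 px, 12 orientations); single- and
multi-scale Gaussian matched filters (profile length 13 px in a 15×15
window, σ = 2.82 or σ ∈ {1.5, 2.0, 2.5}, 12 orientations); and the
morphological black top-hat with a disk structuring element of diameter 19.
Multi-scale/multi-orientation responses take the per-pixel maximum over the
kernel bank.  Parameter-name interpretation for the Gabor/matched families
(K = orientation count over 180°, T = vessel thickness or window, L/I =
kernel length, σ = profile width) follows the Gabor/Gaussian matched-filter
vessel-enhancement literature.

Morphology per response: Otsu threshold → boolean mask; connected
components ("arterial sections", 8-connectivity; specks under 5 px
discarded as noise because perimeter and rectangle estimators degenerate on
them); per component the compactness `C = P²/A`, circularity
`Rc = 4πA/P²` (their product is 4π by construction — asserted exactly) and
elongatedness, the side ratio of the minimum-area rotated rectangle over the
pixel-corner point set (pixels as unit squares, so a 10×2 rectangle scores
exactly 5).  The perimeter comes from the weighted boundary estimator of
`skimage.measure.regionprops`, which keeps digital-circle circularity within
a few percent of 1 (a raw chain-code perimeter overestimates circles by
~5%).  Skeletons are decomposed into branches between endpoints/junctions
("vessel segments", 8-connectivity with redundant diagonal links pruned);
branch length is its pixel count.  Aggregates: section and segment counts,
min/max/median/mean/std of segment lengths, the same aggregates of
per-section segment-length std, and the coefficients of variation of gray
level and gradient magnitude over vessel pixels.  An empty mask produces
0.0 sentinels with a logged warning, never silent zeros.

Default catalog size: 6 + 14 + 8×35 = 300 named features.  The full-scale
catalog of the original study (473 features) is defined externally; this
bank covers every named feature family with a configurable, documented
representative set.

## Synthetic data

* **Feature tables**: balanced labels; informative columns are
  `N(±effect/2, 1)` by class, optional redundant columns add
  `N(0, noise_sd)` jitter to an informative column, the rest are `N(0,1)`
  noise.  The Gaussian shift model is chosen for its analytic Bayes error,
  not realism; pure functions of their seed.
* **Vessel patches**: a dark tube of configurable width around a quadratic
  arc on a brighter background (background 170, vessel depth 90, additive
  Gaussian noise, default σ = 8), with an optional mid-arc width reduction
  (Gaussian bump, relative width 0.12 of the arc) emulating a stenosis.
  `make_patch_bank` randomizes width (5–9 px), curvature (0–0.5) and noise
  identically for both classes; positives draw a narrowing fraction in
  [0.3, 0.7].  The generator returns the ground-truth centerline; tube
  widths are verified against a distance-transform oracle (±0.5 px).

What passing tests on these generators do **not** show: robustness to real
angiographic nuisance (contrast inhomogeneity, background vasculature,
catheters, motion blur), to unbalanced classes, or to the exact 473-feature
catalog of the original study.  They do show that the selector recovers
planted informative subsets, matches exhaustive search on enumerable
problems, and that the diversity mechanism behaves as designed.

## Desk-scale study sizes

Default `RunConfig` mirrors the full-scale configuration (1000 generations,
population 100, selection rate 0.80, SA 1→0 step 0.001, weights 0.90/0.10).
Tests and the acceptance script run reduced problems chosen once: population
16–20, 30–100 generations, 30–50 SA iterations per refinement, 12–30
features, 120–200 samples, 200 patches end-to-end.  The paired
diversity-trend checks use the overfitting-prone testbed described above;
the convergence-delay comparison is intrinsically a narrow-margin median
test at this horizon, since with a fine-grained fitness both arms keep
improving late.

## Numerical and degenerate-input choices

Single seeded generator per run (`RunConfig.seed`), spawned per-trial
streams for batteries; no global RNG state.  Stratified splitting is the
default (the image database is balanced).  PGM comments are tolerated
anywhere in the header; 16-bit rasters are big-endian.  Sorting ties keep
population order; equal-fitness best/worst extremes refine two distinct
individuals.  All-zero fitness vectors fall back to uniform Boltzmann
weights with a warning.

## Known limitations

* The Salem filter is a compatible Hessian-vesselness stand-in (Sato
  formulation); the α/β parameters of the Frangi family do not enter it.
* The GA baseline's crossover/mutation details are conventional choices;
  the original study does not specify its GA configuration.
* Haralick's sum-variance uses the sum-average (not sum-entropy) centering,
  the common modern convention.
* `LinearSVC` (squared hinge, primal) stands in for a generic linear SVM;
  C is fixed, not tuned.
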