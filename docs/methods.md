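# Methods

`flystage` annotates the developmental stage of *Drosophila melanogaster*
embryos in standardized gene-expression images, at three levels of
granularity: the integer stage S ∈ {3,…,17}, an early/late sub-stage
(E/L), and a continuous stage score used to order embryos within a
sub-stage.  This note documents the model, its parameters, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Input model

Inputs are assumed standardized: lateral-view embryos, aligned, anterior at
the left, scaled to 128 × 320 pixels.  Color images are collapsed to
grayscale with ITU-R BT.601 luminance weights (0.299, 0.587, 0.114) and
intensities mapped to [0, 1]; off-size images are resampled bilinearly when
size enforcement is requested.  Segmentation, rotation and view
classification are out of scope.  Stages 1–3 are morphologically
indistinguishable in whole-mount in situ imagery (they differ only in
nucleus count), so they form a single class labelled 3; the usable
alphabet has 15 classes.  Stages 4–16 carry the E/L refinement; the edge
stages 3 and 17 do not.

## Texture features

Each image is filtered in the frequency domain with a log-Gabor bank of
4 scales × 6 orientations.  In polar frequency coordinates (radius r in
cycles/pixel, angle θ) each transfer function is

    G(r, θ) = exp(−log²(r/f₀) / (2 log²σ_f)) · exp(−Δθ² / (2 σ_θ²)),

with Δθ the wrap-around angular distance to the filter orientation θ₀.
Log-Gabor filters have exactly zero DC response, so constant intensity
offsets contribute nothing.  Defaults (exposed in configuration):

| parameter           | default          | meaning                               |
|---------------------|------------------|---------------------------------------|
| `min_wavelength`    | 3 px             | wavelength of the finest scale        |
| `scale_multiplier`  | 2.1              | geometric ladder between scales       |
| `sigma_on_f`        | 0.55             | σ_r/f₀, ≈ two-octave radial bandwidth |
| `theta_sigma_ratio` | 0.66             | σ_θ as a fraction of the π/6 spacing  |

These are the canonical log-Gabor settings from the filter-design
literature; they give overlapping coverage of the frequency plane without
strong ripple.  The magnitude of the complex (analytic) response is used
as the "Gabor image" — the standard phase-invariant texture-energy choice.

Each of the 24 Gabor images is reduced by 8 × 8 block means to
16 × 40 = 640 region values; concatenation gives a 15 360-dimensional
feature vector with the fixed ordering `gabor_index * 640 + block_index`
(scale-major, then orientation; blocks row-major).  The 24 features that
describe one region form a group; the 640 groups drive the group-sparse
penalties.  Features are z-scored per training split before model fitting
(mean/scale recorded per model and applied at prediction time) because the
sparse solvers assume comparable feature scales; raw features are kept for
everything else.

## Classifiers

Binary classifiers predict `sign(w·x + b)` and are trained by minimizing
mean loss + penalty.  Losses: least-square, logistic, hinge.  Penalties:
ridge (ℓ2), lasso (ℓ1), group lasso (sum of group ℓ2 norms, unweighted),
and sparse group lasso (ℓ1 + group).  Group norms are unweighted by group
size since all groups have identical size (24).  Multiclass prediction is
one-vs-rest over the full 15-class alphabet with ties resolved toward the
smaller stage.

Smooth losses are solved by monotone FISTA: accelerated proximal gradient
with backtracking line search on the smooth part, plus a safeguard step
(plain proximal step from the incumbent with momentum restart) whenever the
accelerated candidate would increase the objective, so the objective
sequence is non-increasing.  The prox of the sparse-group penalty is the
exact composition soft-threshold → group soft-threshold.  The intercept is
never penalized by the sparsity terms.

The hinge/ℓ2 configuration (linear SVM) is solved exactly by dual
coordinate descent with a bias-augmented feature, so the intercept carries
the same ridge weight as w there; stopping uses the duality gap, a direct
certificate of primal suboptimality.  The augmentation choice is recorded
in each model's `solver` field.

Regularization strengths default to 1% of the problem's λ_max (the
smallest strength at which the all-zero weight vector is optimal, computed
from the loss gradient at w = 0 with the intercept at its unregularized
optimum); for the sparse-group penalty the ℓ1 and group strengths are set
equal.  Fixed relative strengths keep pool construction cheap and
reproducible; per-member cross-validation is deliberately avoided.
Solver defaults: relative objective change < 1e-6 or 1000 iterations for
standalone fits; pool construction uses lighter settings (80–150
iterations, tol 1e-5) because member accuracy plateaus well before full
convergence and the pool trains hundreds of models.

Solver correctness is validated against independent general-purpose convex
minimizers (`flystage.reference`): ℓ1 terms via a positive/negative
variable split under L-BFGS-B, group norms via epigraph variables under
SLSQP, the SVM via its slack-variable quadratic program.  All seven
configurations agree with these references to ~1e-7 relative on random
small instances.

## Pool, voting, and annotation granularity

The pool crosses 7 algorithms × training ratios {0.5,…,0.9} × 30
stratified train/validation partitions per ratio (1050 members by
default).  Splits are derived deterministically from a master seed and are
shared across algorithms within a (ratio, partition) cell, so algorithm
disagreement is measured on identical data; splits are stratified by stage
(for corpora too small to stratify both parts, a per-class split keeping
at least one training sample per class is used).  Each member's
*confidence* aⁱ is its validation multiclass accuracy; a member whose
training part misses a class is excluded from voting and logged.  If a
member's validation part is empty its training accuracy is used instead.

For a query image each active member votes for one stage; votes accumulate
weighted by confidence into the histogram H over stages 3–17, so
Σⱼ H(j) = Σᵢ aⁱ.  Annotation rules:

* stage: S = argmax H, ties toward the smaller stage;
* sub-stage (4 ≤ S ≤ 16): E when H(S−1) > H(S+1), L otherwise (ties → L);
* stage score: SS = S + ½·(H(S+1) − H(S−1)) / (H(S−1) + H(S+1)), with
  SS = S when both neighbours have zero votes.  SS ∈ [S−½, S+½], increases
  as the later neighbour gains votes, equals S for a symmetric histogram,
  and is < S exactly when the sub-stage is E.  The score is an ordering
  device within a sub-stage, not a calibrated developmental time: a score
  of 7.9 is not necessarily closer to stage 8 than a 6.7 embryo is to 7.
* sub-sub-stage: within each (stage, sub-stage) cohort, annotations are
  sorted by score (stable, input order breaks ties) and split into thirds
  a/b/c, remainders assigned to the earliest thirds.

The stage-score expression is this package's declared convention,
reported in output metadata; any formula that is monotone in the
neighbour-vote asymmetry and confined to [S−½, S+½] would order embryos
identically in rank terms.

## Evaluation criteria

Three nested 0/1 criteria per image: sub-stage accuracy (stage and E/L
both correct), stage accuracy (stage correct), and plus-minus-sub-stage
accuracy (within one half-stage step, where (stage, substage) maps to the
half-stage index 2·stage + {0 for E, 1 for L}).  Edge stages have no
sub-stage: they are scored at stage resolution, and for the half-step
criterion stage 3 sits adjacent to 4E and stage 17 adjacent to 16L.  When
the manual truth lacks a sub-stage on a refined stage, the sub-stage
criterion falls back to stage resolution and the half-step criterion
accepts distance to either half — a documented relaxation for partially
annotated truth tables.  By construction the three accuracies are
monotonically ordered on any dataset.

## Expression maps (GEMs)

A GEM aggregates all images of a group (stage, sub-stage, or stage-score
bin) by pixelwise mean of *inverted* intensities (in situ stains are dark
on light) followed by per-map min–max rescaling to [0, 1], making
composites from groups of different sizes contrast-comparable.  The
aggregation is permutation-invariant and idempotent for duplicated images.
Series at increasing granularity (one map per stage, per sub-stage, or per
score bin with 8 bins per stage) order groups developmentally and skip
empty groups.

## Synthetic corpus

The generator renders 128 × 320 embryos whose appearance is a pure
function of a latent developmental time t ∈ [0, 1]: an elliptical embryo
on a white background carrying (i) a sinusoidal texture field whose
dominant frequency sweeps geometrically across 0.03–0.18 cycles/pixel with
t, exercising the Gabor scales, and (ii) a Gaussian expression band
(σ = 14 px) whose anterior–posterior position interpolates 0.15 → 0.85 of
the image width with t, exercising region-level (group-sparse) feature
selection.  Each stage owns an equal 1/15 sub-interval of t; an image's t
is uniform within its stage's interval and its true sub-stage is E in the
lower half.  Gaussian pixel noise (sd 0.05 by default) is added and
clipped to [0, 1]; clipping rather than renormalization keeps the
noise model simple and bounded.

What passing on this corpus shows: the full chain — texture features,
sparse solvers, confidence-weighted voting, stage-score ordering, GEM
monotonicity — recovers a monotone latent signal from images at realistic
dimensionality, with held-out stage accuracy well above the 1/15 chance
level and high rank correlation between stage score and t.  What it does
not show: performance on real in situ images, whose staining variability,
developmental morphology and label noise are far richer than this
two-factor renderer; accuracies on the synthetic corpus say nothing
quantitative about accuracy on microscope data.

## Problem sizes and validation settings

The end-to-end validation uses 15 stages × 40 images (noise sd 0.05), a
held-out third of the corpus, and a reduced pool of 7 algorithms ×
2 training ratios (0.5, 0.7) × 3 partitions = 42 members trained with the
pool solver settings (80 iterations, tol 1e-5) — a deliberately desk-scale
configuration that preserves every structural element of the full system
(all seven algorithms, shared stratified splits, confidence weighting).
Solver cross-checks run 20 random instances (n ≤ 50, d ≤ 20) per
configuration.  Determinism is checked by training and annotating twice
from the same master seed and comparing output bytes.

## Known limitations

* The hinge configuration ridge-penalizes the intercept (via
  augmentation); the smooth-loss configurations leave it unpenalized.
* Group penalties assume disjoint groups; overlapping or hierarchical
  structures are not supported.
* Vote confidences are raw validation accuracies; no calibration or
  ensemble pruning is applied.
* The stage score is a within-sub-stage ordering, not an absolute clock;
  comparing scores across distant stages is not meaningful.
* The package assumes standardized input and performs no alignment or
  quality control of its own.
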