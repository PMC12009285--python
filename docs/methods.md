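# Methods

This note records the models implemented in `thermofuse`, the parameter
choices that matter, and what the synthetic experiments do and do not show.

## The hybrid optimizer (RHDAO)

RHDAO minimizes a black-box objective over a box `[BL, BU]^d` with a
population of candidates. Per generation:

1. Evaluate all candidates; identify best fitness `BF`, worst `WF`
   (ties broken by lowest index) and the best agent (leader / core
   dandelion).
2. For each candidate compute `angle = 360·(CF − BF)/(WF − BF)` (0 when
   `WF = BF`), random-walk it by a uniform step in ±36° (10 % of the angle
   range, clamped to [0, 360]), and route: **RHSO** if `angle > 180`
   (strictly), otherwise **DA**. The perturbation keeps the switching
   stochastic near the boundary; the worse half of the population therefore
   tends to take RHSO moves, the better half DA sowing.
3. RHSO moves: the leader proposes `l₁·position` with `l₁ ~ U[0,1]`; a
   member proposes `(1 − circle)·position` with
   `circle = √((s₂cos a)² + (s₂sin a)²) = |s₂|`, `s₂ ~ U[0,1]`,
   `a ~ U[0,360]`. Proposals are clamped to the box and accepted greedily
   (never replace a better incumbent). The literal contraction pulls toward
   the origin; an opt-in `recentered` variant contracts toward the leader
   instead, useful for problems whose optimum is far from the origin. It is
   off by default to preserve the canonical arithmetic.
4. DA sowing: each routed candidate sows
   `n = max(min_seeds, ⌊max_seeds·(h_max − h + ε)/(h_max − h_min + ε)⌋)`
   seeds uniformly within its radius per dimension (clamped). The core
   dandelion's radius starts at the search-space diameter, grows by
   `f ∈ [1, 1.1]` after an improving generation and withers by
   `v ∈ [0.8, 1)` otherwise; assistant radii update as
   `ω·prev + (‖core‖_∞ − ‖self‖_∞)` with `ω = 1 − he/he_max` decaying with
   the evaluations spent (`he_max` is an upper bound on the run's budget:
   `pop·(iterations+1)·max_seeds`), floored at `10⁻⁶` of the diameter so
   sowing never collapses.
5. Elitist truncation keeps the `population_size` best of parents ∪
   proposals ∪ seeds; the best-so-far trace is therefore non-increasing.

Defaults: population 30, 25 iterations, `min/max_seeds = 2/10`,
`f = 1.05`, `v = 0.9`. `ε` is the smallest positive normalized double (its
only role is guarding a zero denominator). Pure `rhso` and `da` modes
bypass the routing for ablation; branch counters in the run history make
the routing auditable. Maximization objectives are negated.

The degenerate-population case (`WF = BF`) assigns angle 0 to everyone, so
a constant objective exercises only the DA branch — by design, since no
fitness gradient exists to rank hyraxes.

## Threshold search exactness

The useful thresholds of an `r`-bit image form a discrete set of `2^r`
levels, and the search rounds real positions to the nearest level. A
metaheuristic alone cannot *guarantee* hitting the exact argmax, so
`optimal_threshold` memoizes the objective per integer level, runs RHDAO,
and then spends any remaining evaluation budget (default: enough to cover
the whole range) on levels the optimizer never visited, returning the best
overall. With a budget ≥ the number of levels the result provably equals
the exhaustive-search optimum; `rhdao_only=True` disables the completion
sweep for studying the raw optimizer (the acceptance report includes both
match rates — the raw optimizer lands on the exact best integer in only a
minority of runs, though always very close in objective value).

The unsupervised objective is Otsu's between-class variance; the supervised
alternative is Dice overlap with a reference mask. The default search range
is the full gray range; the narrow `[200, 255]` window quoted for the
original clinical setting is exposed as `CLINICAL_THRESHOLD_BOUNDS` but is
meaningless for arbitrary synthetic inputs.

## Preprocessing

CLAHE splits the image into a tile grid (edge-reflection padding when the
dimensions do not divide, cropped after), clips each tile histogram at
`β = (tile_pixels/N)(1 + (α/100)(L_max − 1))`, redistributes the excess
uniformly over the bins, equalizes per tile with the cumulative-count
mapping, and blends mappings bilinearly between tile centers (edge tiles
replicate). With a 1×1 grid and no effective clipping it reproduces global
histogram equalization to within one gray level. Defaults: 8×8 tiles, 256
bins, clip factor α = 40 %, max slope 4.

The classification pipeline applies **CLAHE only** by default: global
histogram equalization maps every image onto the same flat intensity
distribution, which destroys the absolute hyperthermia signal (how hot the
hottest region is relative to a fixed scale) that separates lesional from
normal thermograms. CLAHE's clip limit bounds noise amplification while
preserving intensity ordering. Global equalization remains available as a
module function, a CLI flag and a pipeline toggle for visualization.

## Feature branches, fusion, ensemble

The three extractors are fixed-seed, deterministic, desk-scale stand-ins
that keep the architectural signature of their namesakes while remaining
pure functions (64 features each by default):

* **branch 1** (VGG-style): two stages of seeded non-negative 3×3
  convolutions + ReLU + 2×2 max pooling on the 32×32-resampled image,
  max-pooled into a coarse grid. Max pooling keeps extremal local
  responses — hot spots — approximately translation invariant.
* **branch 2** (ResNet-style): the image's intensity-quantile profile (64
  evenly spaced quantiles, position-invariant, upper tail = hot spots)
  through three residual stages `n → tanh(Wn) + n`.
* **branch 3** (DenseNet-style): block-mean summary through densely
  connected stages (each consumes the concatenation of all previous
  outputs) with global average pooling over stage outputs.

ImageNet-pretrained backbones are deliberately out of scope; the package's
contribution is the optimization/fusion scaffolding, and the `FeatureSet`
contract lets users substitute real pretrained features.

Fusion is the element-wise weighted sum `SF = W₁f₁ + W₂f₂ + W₃f₃` with
scalar weights in [0,1] (a `literal_typo` flag reproduces a misprinted
variant that pairs `W₂` with `f₃`, for forensic comparison only). The
ensemble trains three one-hidden-layer feed-forward heads (scikit-learn
MLP, L-BFGS, seeded per head) on the same `SF` and sums their per-class
probabilities; argmax with lowest-index tie-break decides. Heads differ
only by seed — their diversity comes from initialization, which is enough
at this scale.

Hyperparameter tuning maximizes validation accuracy over the genome
(weights, epochs [50,100], hidden neurons [5,255], activation index with
floor decoding over {relu, sigmoid, tanh}; optionally a segmentation
threshold gene when a supervised segmentation fitness exists — with an
unsupervised fitness the threshold is fixed before feature extraction,
since accuracy cannot be back-propagated to it). The space midpoint (and,
for fusion-weight-only tuning, the equal-weights point) is injected into
the initial population, so elitism guarantees the tuned result is never
worse than that reference.

## Synthetic phantoms

A phantom is `clip(background + Σ lesion bumps + vignette + noise)`
quantized to 8 bits (16-bit optional): background = mean level 120 plus
2–4 low-frequency cosine modes of total amplitude 20 (body-surface
temperature gradients); lesions = isotropic Gaussian bumps of σ 5–10 px
and peak delta 50–70 gray levels (hyperthermic by construction); radial
vignette of strength 10; white noise σ = 10. The default cohort is
96×96 px, 20 normal / 20 abnormal, i.e. a lesion contrast of at least 5×
the noise level — a clearly-imageable lesion, which is the regime the
method targets. Ground truth marks the half-maximum disk of each bump
(radius `σ√(2 ln 2)`); the label is abnormal iff any lesion is present.
Per-image seeds are hashed from the master seed, so cohorts reproduce
file-for-file.

What the phantoms do **not** model: patient anatomy and pose, the Pennes
bioheat equation, camera calibration drift, multi-frame acquisition
protocols, benign hyperthermic confounders (inflammation, vasculature) and
class imbalance. Passing tests therefore demonstrate the pipeline's
mechanics and its ability to recover a clean planted signal — not clinical
performance.

## Problem sizes and numerical choices

The test suite and acceptance script use: 20 images for the
threshold-exactness check, 20 seeds of the 5-D sphere benchmark at the
default population/iteration budget, 1000 random draws for the circle and
metric-suite identities, and 10 independent 40-image cohorts for
end-to-end recovery, with hyperparameter tuning scaled to a population of
5 over 4 generations with 1–3 seeds per dandelion — enough for the
optimizer to act while keeping a full 10-seed study around a minute.
Tolerances: exact identities are asserted at 1e-12 or to double precision;
rounding-mediated contracts (histogram-equalization idempotence) at one
gray level. Ratio metrics with empty denominators are NaN with a warning,
never silently zero. All tie-breaks (argmax, truncation, best/worst
identification) resolve to the lowest index.

## Known limitations

* The literal RHSO contraction is origin-biased; greedy acceptance makes it
  harmless off-center, but on problems whose optimum lies away from the
  origin the RHSO branch contributes little (the `recentered` variant
  addresses this).
* Head training uses L-BFGS epochs as an iteration cap, not literal
  epoch-by-epoch gradient descent; at 40-sample scale the distinction is
  immaterial but the epoch gene's effect is correspondingly coarse.
* The metric suite treats multi-class input by one-vs-rest macro-averaging;
  the pipeline itself is binary (normal/abnormal).
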