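# Methods

## Model

A classifier is a pair: a symbolic discriminant expression and a threshold
rule. The expression is a tree over building blocks — feature references,
real constants, and the binary arithmetic operators {+, −, ×, protected ÷} —
whose scalar output per sample is the *test value*. The threshold rule
orders the n classes by the ascending median of their training test values,
places a threshold at the mean of each successive pair of medians, and maps
a test value to the class of the interval it falls in. Each of the n−1
interval boundaries can belong to either the lower or the upper class;
fitting enumerates all 2⁽ⁿ⁻¹⁾ boundary-direction vectors and keeps the one
with the highest training accuracy (ties resolved lexicographically,
all-non-strict first, so fits are reproducible). The rule partitions the
real line, so every finite test value receives exactly one class.

Fitness is two-objective: training accuracy (fraction correct for the
multi-class case; a balanced-accuracy helper is provided for binary use)
to be maximized, and complexity — the total building-block count of the
expression — to be minimized. Solution a dominates b when it is no worse
in both objectives and strictly better in at least one.

### Assumptions

- A single scalar projection of the features, thresholded along one axis,
  can separate the classes; the evolutionary search compensates for
  non-monotone or multi-feature structure by composing features into one
  expression.
- Class medians are meaningful location summaries, i.e. within-class
  test-value distributions are roughly unimodal.
- Classes are reasonably balanced; plain fraction-correct accuracy is the
  fitting criterion (macro-averaged metrics are out of scope).

## Evolution

Solutions occupy a D×D toroidal lattice, so every cell has exactly eight
Moore neighbors. Per generation, on a frozen copy of the grid, every cell
whose fitness dominates all eight neighbors writes mutated copies of
itself into those eight positions; each copy is re-fitted (medians,
thresholds, flags) and re-scored on the training data. Cells not claimed
by any dominator persist unchanged. When several dominators claim the same
cell, the winner is chosen deterministically: higher accuracy, then lower
complexity, then smaller (row, col). Two dominators can never be adjacent
(mutual domination is impossible), so a dominator is never overwritten.

Mutation applies one of three structural edits with configurable
probabilities (defaults add 0.25, remove 0.25, swap 0.5; the remainder is
a no-op): *add* wraps a random subtree in a new operator with a fresh
random leaf as sibling, *remove* hoists a random internal node's child
over its parent (a single leaf cannot shrink further), *swap* replaces a
random leaf with a fresh leaf or a random operator symbol with another.
Subtree crossover (`recombine`) is implemented and tested as part of the
expression engine but the tournament propagates by mutation only; the
grid-local domination step is defined in terms of mutated copies, and
keeping recombination out of the loop keeps the update rule minimal and
exactly reproducible. The rates are fixed per run; a self-adaptive
controller for them is a non-goal.

An external elitist archive maintains the Pareto front over every
classifier ever evaluated; consequently its best accuracy is monotonically
non-decreasing over generations. One member is kept per (accuracy,
complexity) point — first seen wins — which bounds the archive by the
number of distinct complexities on the front. A safety cap (default 500)
truncates by dropping the interior member in the tightest accuracy gap,
never the extremes; in practice the cap does not bind.

*Pareto levels* chain runs: level 1 starts from a random grid; level L+1
tiles the level-L archive into its initial grid (cycled if the archive
exceeds D², padded with random trees otherwise) and evolves again. Since
the seeded members are re-evaluated on the same data, the best accuracy at
level L+1 is at least that of level L. Runs stop after a fixed generation
count; wall-clock-budgeted stopping is excluded as hardware-dependent.

### Numerical choices

- **Protected evaluation.** Division returns 1.0 when |denominator| <
  1e−9; every operator output passes through a clamp that maps NaN to 0.0
  (its sign is undefined) and limits magnitude to 1e12. The clamp applies
  at every internal node, so arbitrarily deep trees on inputs up to ±1e6
  cannot overflow: evaluation always returns a finite value.
- **Constants** are drawn uniformly from [−10, 10] by default — bounded
  constants keep threshold magnitudes stable.
- **Initial trees** use grow-style construction with leaf probability
  rising linearly with depth (default maximum depth 4), giving the grid a
  spread of sizes.
- **Median ties.** Classes with equal medians keep their first-appearance
  order; the degenerate threshold equals the shared median and the
  boundary flags still decide ownership, keeping the rule total.
- **Determinism.** A single `numpy.random.Generator` threads through
  generation, mutation, and grid construction in row-major order, so
  (dataset, config, seed) reproduces archives bit-for-bit. Cross-validation
  derives one child seed per fold from a master generator.

## Preprocessing

Raw-count matrices are filtered to features with a count of at least 5 in
at least one sample, then transformed with log2(x + 1). The log transform
is the provided variance-flattening transform; matrices transformed
externally (e.g. by a count-model variance-stabilizing transformation) can
be supplied directly. "Expert knowledge" is the top-k (default 100)
features by one-way ANOVA F-statistic with p < 0.05, computed with
(n−1, N−n) degrees of freedom; during evolution, feature leaves are drawn
from this set with probability 0.8 (configurable) and from all features
otherwise — biasing rather than restricting the search, so features
outside the screen remain reachable.

## Evaluation protocol

Repeated stratified k-fold cross-validation (default 10 repetitions × 5
folds = 50 evaluations). Stratification prevents empty-class training
folds with small, near-balanced class sizes; each class must contain at
least k samples. Everything fitted — the expert screen and the classifier
(expression + thresholds + flags) — uses the training split only; the
frozen rule is applied unchanged to the test split. Per fold the archive
member with the highest training accuracy is selected (ties: fewest
building blocks, then smallest expression string). Aggregates: mean test
accuracy, mean selected-feature count, and stability as the mean Tanimoto
similarity over all unordered pairs of per-fold feature sets (the natural
reading of "average across all feature sets" for a pairwise measure).
A constant-only expression contributes an empty feature set; such sets are
excluded from the stability mean, which is NaN if fewer than two non-empty
sets remain. Feature-frequency tables across repeated runs exclude
features appearing in only one run.

## Synthetic data

The generator emulates a transformed multi-class RNA-Seq experiment: p
exchangeable noise features, of which a chosen few are informative.

- **Gaussian mode** (transformed scale): noise is N(0, 1); an informative
  feature's class-c mean is c·δ with δ the effect size in noise-SD units.
  Class means are therefore ordered and evenly spaced along the class
  index — exactly the monotone geometry a single thresholded feature can
  separate, the easy regime for the median rule.
- **Count mode:** negative-binomial counts (variance μ + αμ²; dispersion
  α = 0.2 by default, a typical bulk RNA-Seq overdispersion) around a
  baseline mean of 50; informative class-c means scale by exp(c·δ·√α),
  approximating a δ-SD shift on the log scale. This path exercises the
  low-count filter and log transform.
- **Non-monotone mode** permutes each informative feature's class-mean
  profile, producing signals no single thresholded feature separates and
  forcing composite expressions.

Defaults (4 classes × 30 samples, 500 features, 6 informative, δ = 2,
Gaussian) define the reference recovery experiment used by the acceptance
script at a reduced evolution budget (16×16 grid, 200 generations per
fold, 1 repetition of 5-fold CV) — sizes chosen so the full protocol runs
in seconds on one CPU while leaving the recovery signal comfortably above
chance. What passing these synthetic experiments does *not* show: the
generator has no library-size variation, batch structure, or gene–gene
correlation, so stability and accuracy on real data with correlated
co-expressed genes may differ (correlated informative features make
selection stability intrinsically lower).

## Known limitations

- The two-objective fitness weights accuracy and complexity implicitly
  through domination; there is no tunable trade-off weight, which can
  under-fit datasets needing larger feature sets.
- Grid evolution can stall when neighborhoods fill with equal-fitness
  copies (strict domination becomes rare); additional Pareto levels or a
  different seed restart the search.
- Flag-vector enumeration is exponential in the number of classes
  (2⁽ⁿ⁻¹⁾ per candidate); fine for the intended n ≤ ~10, not for
  hundred-class problems.
- The wrap-around border and the synchronous update with deterministic
  conflict resolution are design choices where the grid tournament is
  defined loosely; both were chosen so that every cell has exactly eight
  neighbors and runs are exactly reproducible.
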