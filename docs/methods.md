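# Methods

## Model

The package treats each feature of a tabular classification dataset as a
fuzzy equivalence relation over the `m` objects. A continuous feature `f`
relates objects by `E_f(x_i, x_j) = exp(−|x_i − x_j|)`; a nominal feature
(and always the class, whatever its numeric encoding) by the crisp equality
relation. The relation matrix is symmetric, reflexive and `[0,1]`-valued;
for a feature subset, relations are intersected entry-wise with the minimum
t-norm. All quantities are computed from these matrices at full floating
precision; two-decimal rounding appears only in human-readable output.

Three criteria drive selection:

* **Fuzzy entropy** `H(f) = (1/m) Σ_i log2(m / |[x_i]|)`, where `|[x_i]|`
  is the row sum of the relation matrix. The base-2 choice is fixed by the
  package's reference example: the printed values 0.34 (feature) and 0.97
  (binary class on 5 objects) arise only with base 2.
* **Fuzzy mutual information** between two relations, with the intersection
  realized as the element-wise minimum of rows. Per-object log terms are
  summed without clamping; for degenerate inputs the sum can in principle be
  marginally negative, which is reported as computed.
* **Fuzzy-rough dependency** `γ`: the mean over objects of the positive
  region, itself the per-object supremum over crisp class sets of the lower
  approximation under the Łukasiewicz implicator `min(1, 1 − a + b)`.
  `γ` is normalized by the object count `m`, the standard fuzzy-rough
  convention, and is monotone non-decreasing under subset growth (adding
  features can only shrink the min-relation, and the implicator is
  non-increasing in its first argument) — a property the test suite checks
  exhaustively at small `n`.

## Selection procedures

**FWRFS** produces a full greedy ranking. The first feature maximizes
relevancy `I(f;C)`; each subsequent pick maximizes
`I(f;C) − (1/|S|) Σ_{s∈S} w(f,s) I(f;s)`. Two weighting modes exist:
`"wrfs"` (default) with `w(f,s) = I(s;C)/(I(f;C)+I(s;C))`, balancing the
selected and candidate relevancies, and `"uniform"` (`w ≡ 1`, the mRMR-style
mean-redundancy penalty). The weighted form is the package's reading of the
"weighted relevancy" idea the ranking derives from; since the exact weight
formula is not uniquely fixed by its source, both modes are exposed and the
mode is recorded in run logs. If both relevancies are zero the weight
defaults to 1/2.

**L-FRFS** greedily grows a subset by maximal `γ` gain, stopping when the
best addition improves `γ` by at most `tol = 1e-12` or `γ` reaches the
full-set value within `tol`. Exact floating-point equality comparisons are
avoided deliberately: monotone `γ` sequences differing only by rounding
noise would otherwise loop or overrun. The greedy search is not guaranteed
optimal; tests assert only that its final `γ` never exceeds the exhaustive
best at matched subset size.

**MIN combination** scores each feature by the minimum of its two positions;
a feature absent from the (possibly short) dependency subset falls back to
`n + pos_R1(f)` there, so its combined score is its FWRFS position. Any
finite penalty larger than `n` yields the same order; the finite choice
keeps scores total and serializable. Ties are broken by FWRFS position, then
feature index — all procedures are deterministic, with greedy ties resolved
toward the lowest feature index.

**Threshold**: the selected subset is the top `⌈n/2⌉` of the combined
ranking (the median position; for even `n` the "nearest integer" is taken
as `n/2`, overridable via `k`). The companion truncation rule — cut a
dependency subset longer than the threshold back to its first `k`
additions — lives in the evaluation harness (`truncate_subset`), not in the
selector, so the selector's output always reflects its own stopping rule.

## Stability protocol

`stability_experiment` spawns `p = 10` child seeds from a master seed. Each
run perturbs a uniformly random `⌈0.10·m⌉` subset of every continuous
feature's values by additive `N(0, σ_f)` noise (`σ_f` the feature's sample
SD; nominal and constant features untouched), reruns the selector, and keeps
its top `r` features (default: the median threshold). Agreement is scored by
the Kuncheva index `(w·n − r²)/(r(n − r))`, averaged over all unordered
pairs; the index is 1 for identical subsets and has expectation 0 for random
ones (verified by Monte Carlo in the tests). The noise wording this protocol
implements is ambiguous between perturbing 10% of cells with `σ_f` noise and
perturbing all cells with `0.1·σ_f` noise; the former is the default
(`noise_mode="cells"`), the latter available as `noise_mode="scaled"`, and
the mode is logged. `fraction=0` skips injection, so any deterministic
selector scores exactly 1. A convenience aggregate (`stability_profile`)
averages stability over the first-half thresholds `r = 1 … ⌈n/2⌉`.

## Evaluation harness

`evaluate_selection` runs repeated stratified k-fold cross-validation
(defaults 10×10) of pluggable classifiers on a fixed feature subset.
Selection precedes the folding by default — the subset is chosen once on the
full data, matching the upstream-selection design the protocol mirrors — and
a `reselect` callback reruns selection inside each training fold for
leakage-free comparisons. Metrics are accuracy, F-measure (β = 1) and AUC;
multi-class F-measure and AUC are macro-averaged (uniform class weighting),
a choice the harness makes explicitly since no averaging rule is otherwise
fixed. A degenerate fold whose truth contains one class scores AUC 0.5 by
convention. The default classifier set is GaussianNB, SVC (with probability
estimates), 3-nearest-neighbours and a CART decision tree from scikit-learn,
with fixed random states; any estimator with `fit`/`predict`
(/`predict_proba` for AUC) plugs in.

## Synthetic-data generator

`generate_synthetic` plants known structure for property tests: informative
features are class-conditional gaussians with unit SD and class means
`effect_size` apart (classes spread along a line); each redundant feature is
`ρ·z(parent) + √(1−ρ²)·noise` of an informative parent (round-robin);
irrelevant features are independent standard normals. Defaults — `m = 200`,
2 informative at `effect_size = 2.0`, 1 redundant at `ρ = 0.95`, 3
irrelevant, 2 classes — give a clearly separable but not trivial task: 2 SD
separation leaves real class overlap, and `ρ = 0.95` makes the redundant
copy nearly as relevant as its parent, so demoting it requires the
redundancy penalty rather than relevancy alone. The generator is
deterministic per seed. What it does **not** emulate: nominal features mixed
with continuous ones, heavy-tailed or skewed marginals, feature-scale
heterogeneity, label noise, and class imbalance beyond sampling variation —
recovery and stability results on this generator therefore show the
machinery behaves as designed, not that it wins on any particular real
dataset.

## Numerical and design choices

* Raw feature values enter the similarity kernel by default; an optional
  min–max-to-[0,1] rescale (`Dataset.scaled_minmax`, CLI `--scale minmax`)
  is provided for data whose feature scales differ wildly, since `exp(−d)`
  saturates for distances ≫ 1. Its use is logged.
* Missing values are rejected loudly by default; `impute=True` fills
  median (continuous) / mode (nominal).
* The class is always crisp, even when encoded numerically; fuzzy class
  partitions are out of scope.
* `inf`/`sup` are `min`/`max` over the finite object set.
* Relation matrices validate symmetry, reflexivity and range on
  construction, so downstream code can assume them.

## Problem sizes

The test suite runs entirely on the built-in 5-object example, random
instances with `m ≤ 30`, and synthetic datasets of 100–200 objects and 6
features over 20 seeds; the whole suite completes in well under a minute.
Exhaustive-subset checks (monotonicity, greedy-vs-best) use `n ≤ 5`, where
enumeration is exact. These sizes were chosen as the smallest at which the
stochastic properties (recovery rates, stability nulls) are reliably
resolved; the algorithms themselves are `O(m²)` per relation matrix and
`O(n²)` relation evaluations per ranking, and scale to ordinary benchmark
tables unchanged.

## Known limitations

* The exponential kernel has no bandwidth parameter; features on very large
  scales collapse toward the identity relation (everything looks distinct)
  unless rescaled.
* Greedy search in both selectors can miss interacting feature pairs that
  are only jointly informative.
* Relation matrices are dense `m × m`; memory grows quadratically with the
  number of objects, which is the practical ceiling (tens of thousands of
  rows) rather than feature count.
* Regression targets and multi-label classes are unsupported.
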