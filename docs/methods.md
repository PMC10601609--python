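# Methods

## Model and procedure

`svmga` selects feature subsets for a binary linear-SVM classifier by
minimizing, with a genetic algorithm over d-bit inclusion masks,

FF(S) = 1/ACC_train(S) + a·(m/d) + b/width(S),

where m = |S|, ACC_train is the training accuracy of a soft-margin linear
SVM trained on the training split restricted to S, and width(S) = 2/‖w‖₂ is
the geometric margin of that SVM's decision boundary w = Σᵢ αᵢyᵢxᵢ taken
from the dual solution. The three terms encode accuracy, parsimony and a
training-independent proxy for generalization: under class-conditional
Gaussian classes, a wider separating margin in the selected subspace means
a smaller overlap probability between the classes, so maximizing the margin
(minimizing b/width) steers the search toward subsets that should
generalize, without consulting held-out data. The test split is used once
per epoch to record the best chromosome's accuracy for the trajectory; that
record feeds nothing back into the search, and `evaluate_fitness` accepts
only the training partition, so test-blindness holds by construction.

Two literal variants of the penalty terms are selectable. `ff2_form=
"literal_reciprocal"` scores a/m, which *decreases* with subset size and so
rewards large subsets; the default a·(m/d) implements the declared goal of
minimizing cardinality and is normalized so a is comparable across
dimensionalities. `ff3_form="reciprocal_weight_norm"` scores b/‖w‖₂ —
interpreting the margin quantity as the weight-vector norm rather than the
geometric width. Only the width reading makes minimizing FF3 maximize the
margin, so it is the default; the alternatives exist for fidelity
experiments with the historical formulation.

## Genetic algorithm

Generational loop with elitism (default 1 copy of the best chromosome
carried over, making the best-fitness trajectory monotone). Parents are
drawn either by roulette with probability ∝ 1/FF (the minimization
transform of fitness-proportional selection; default) or by linear rank.
Reproduction is single-point crossover applied with probability
`crossover_rate` (default 0.8) at a locus uniform on 1..d−1, otherwise the
first parent is copied; mutation flips each bit independently with
`mutation_rate` (default 0.01), and an all-zero mask is repaired by
switching one uniformly chosen bit on — empty subsets are never evaluated.
The initial population draws bits Bernoulli(`init_density`, default 0.5).
Reference full-scale settings are 1200 chromosomes × 1005 generations;
desk-scale experiments in the test suite use 100–250 chromosomes and
25–150 generations, which suffice for the d ≤ 60 problems they study.
Degenerate evaluations (zero training accuracy, or a zero weight vector,
which arises e.g. for constant feature columns) receive a finite penalty —
`penalty_factor` (default 10) times the worst finite fitness of the current
generation, or 10⁶ when a generation has none — so selection never sees an
infinity and no run aborts mid-search. Fitness values are memoized per
mask: the fitness is a pure function of the mask given the training split
and config, so memoization changes no result, only runtime. The whole
trajectory is a pure function of (dataset, config, seed); a single
`numpy.random.Generator` seeded from `GAConfig.seed` drives every draw.

Choosing the weights a and b matters. With the default a = b = 0.05 the
penalty terms stay well below FF1, so a run on separable data converges to
fitness ≈ 1 while only weakly pruning. For subset-*recovery* experiments
the package's examples use a = b = 1 with rank selection: a per-feature
cardinality cost a/d that falls between the margin gain of a noise feature
and that of a signal feature makes the planted subset the global optimum
(measured on the generated cohorts: a noise feature changes b·(1/width) by
≲0.01, a signal feature by ≳0.03, and a/d = 1/60 ≈ 0.017 sits between),
and rank selection supplies workable selection pressure where reciprocal-
fitness roulette is nearly uniform (FF differences of ~1%).

## SVM engine

The dual problem is solved by libsvm's SMO (scikit-learn `SVC`,
`kernel="linear"`); multipliers, support set, w and bias are read off the
fitted model, and dual feasibility (Σαᵢyᵢ = 0, 0 ≤ αᵢ ≤ C) is asserted in
tests, along with agreement of the 2-D margin with a brute-force
maximum-margin grid search to 1e-4 relative. C defaults to 1.0 (soft
margin guards pathological subsets on n ≪ d data); C = 1e6 gives
hard-margin behaviour for geometry tests. `train_linear_svm` solves on the
matrix it is given — margins are then covariant with input scale — while
the GA fitness path and the filter sweep z-score each active feature with
training-split statistics first (test data transformed with the same
statistics), because margin comparisons across heterogeneous feature
subsets are meaningless on raw scales.

A caution on margin monotonicity: the empirical hard-margin width never
decreases when features are added (the old separator persists in the larger
space), and in finite samples a pure-noise dimension buys a small positive
gain (~3% at n = 38). The margin term therefore cannot by itself prune
noise features; the cardinality term supplies that pressure, which is the
basis of the weight-window analysis above.

Benchmark classifiers for the filter comparison: a decision tree capped at
13 internal nodes (`max_leaf_nodes=14`), an RBF SVM with γ = 1/m, a linear
SVM with C tuned by 3-fold cross-validation over {0.01, …, 100}, and 4-NN
(Euclidean, unweighted) with exact ties broken toward the nearest
neighbour's label.

## Mutual-information filter

Per-feature MI with the binary outcome is estimated by equal-frequency
(quantile) binning with `n_bins=8` and a plug-in entropy, reported in bits;
features with ≤ n_bins distinct values are treated as categorical.
Equal-frequency binning is invariant to monotone rescaling, which suits
features of unknown scale; the plug-in estimate carries the usual positive
bias of order (bins−1)/(2n ln 2), small at the n involved. A k-NN
estimator (scikit-learn's) is available as an alternative backend. Ranking
ties break by ascending feature index so rankings are deterministic. MI is
computed on the training split only; using all samples would leak test
labels into selection and break comparability with the wrapper. The
elimination sweep retrains the chosen classifier at every retained size
m = d, d−step, …, 1 and records train, test and overall accuracy, where
"overall" is the accuracy over the union of both splits (equivalently the
sample-size-weighted mean of the two).

## Synthetic cohorts

The generator emulates the tabular structure of a small clinical cohort:
class-conditional multivariate Gaussian features, default 56 samples × 248
features with 32 outcome-positive, and a default stratified split of
exactly 23 positive + 15 negative training samples (test 9 + 9). A planted
block of `n_informative` columns receives a class mean shift of
`effect_size` × `noise_sd` (so effect sizes are in within-class sd units);
all other columns are i.i.d. class-independent noise. The informative block
can be equicorrelated (`correlation` ρ via a shared Gaussian factor), and
`effect_direction="alternating"` flips the sign of the shift on every other
informative column. Alternating shifts in a positively equicorrelated block
produce the combinatorial regime that separates filter from wrapper
methods: each marginal separation is δ, but the best linear combination
separates at ≈ δ√(k/(1−ρ)) (a zero-sum contrast cancels the shared factor),
e.g. δ = 0.6, k = 5, ρ = 0.85 gives ≈ 3.5 sd jointly versus 0.6 sd
marginally. Labels are {0, 1} at the I/O boundary and {−1, +1} inside the
SVM layer. The generator does not emulate real physiological-feature
properties — heavy tails, heteroscedasticity, block correlation among
nuisance features, label noise — so passing recovery tests demonstrate
correctness of the machinery under the stated Gaussian assumptions, not
performance on clinical data.

## Numerical choices and limitations

Zero-variance columns are given unit scale during standardization rather
than dividing by zero; a weight vector with ‖w‖₂ < 1e-10 is flagged
degenerate and `margin_width` refuses it. Dual feasibility is checked to
1e-6, reflecting libsvm's solver tolerance. CSV round-trips use pandas'
round-trip float parsing so written cohorts reload bit-identically.

The method assumes a linear decision boundary in the selected subspace
(kernel margins are out of scope for the fitness), assumes approximate
class-conditional normality for the margin-overlap argument, and inherits
the GA's usual caveat: with few chromosomes relative to d the search
settles near its starting combination, so population size must grow with
the feature space. Exhaustive-enumeration agreement is verified at d ≤ 8;
at realistic d the GA's optimum is a well-tested heuristic, not a
certificate.
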