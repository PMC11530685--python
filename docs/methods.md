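# Methods

`sportfs` evaluates the effect of exercise participation on physical-fitness
indicators by ranking indicators with a modified random forest and tuning
model parameters with an opposition-based-learning artificial raindrop
optimizer (OBL+ARA). This note documents the models, the choices made where
the design was genuinely open, and what the synthetic experiments do and do
not demonstrate.

## The weighted random forest

Trees are grown CART-style on bootstrap resamples (n draws with
replacement; the out-of-bag (OOB) set is the complement). At every node
`features_per_split` candidate indicators are sampled without replacement
(default ⌈√d⌉) and the split threshold maximizing base-2 information gain

    g(X, A) = Ent(X) − Ent(X | A),     Ent(X) = −Σᵢ pᵢ log₂ pᵢ

is chosen over midpoints between sorted distinct values. Recursion stops at
purity, the depth limit, the minimum leaf size, or when no sampled candidate
offers positive gain. Ties in the argmax go to the lowest column index so
every construction is reproducible.

**Weighted voting.** Each tree t receives a scalar weight
w_t ∝ (1 − OOB error of t), normalized to Σ w_t = 1. A forest prediction is
argmax over classes of Σ_t w_t · 1[tree t votes the class] — a 1×n_trees
weight row "convolved" with the n_trees×K one-hot vote matrix. With uniform
weights this is exactly majority voting. A tree with an empty OOB set (rare
at realistic n) is weighted by its in-bag accuracy with a logged warning.

**Importance.** Two per-node Gini accumulations are maintained while
growing, where Gini_m = 1 − Σ_k p²_mk:

* `as_printed`: the raw unweighted delta `Gini_m − Gini_l − Gini_r`, summed
  over the nodes splitting on each feature and over trees;
* `mdi` (default): the standard mean decrease in impurity,
  `(m/n)·(Gini_m − (n_l/m)·Gini_l − (n_r/m)·Gini_r)`.

The raw unweighted delta is negative whenever the two children are nearly
as impure as their parent (their Ginis add), and is +Gini_m for any split
into pure children regardless of node size. Accumulated over a deep forest
this systematically rewards features that purify two-sample leaves — mostly
noise — and penalizes the large informative splits near the root; on the
default synthetic cohort it ranks *none* of the five planted indicators in
the top seven. It is therefore exposed faithfully as an option and as the
`node_importance_delta` evaluator, but the forest-level ranking,
elimination, and reports default to `mdi`, which is the form under which
importance ranking is a meaningful feature-selection signal. Raw scores are
clipped at zero and normalized to sum to one.

**Noise-perturbation importance** permutes one feature's column within each
tree's OOB rows and reports the mean growth in OOB error. Permutation
destroys the feature–label association while preserving the marginal
distribution; an additive-Gaussian perturbation is available behind
`mode="gaussian"`.

**Iterative elimination** removes the bottom ⌈fraction × d_current⌉
features by normalized importance each round, recording the stratified CV
accuracy trajectory, until the round budget or a single feature remains.

## The OBL+ARA optimizer

Candidates ("raindrops") carry their objective value as potential energy
and flow toward a fixed-capacity elite pool (default 20) kept sorted by a
bubble-pass update: a candidate better than the worst member replaces it
and sinks to its position. Per iteration each raindrop takes 1..`max_flow`
(default 3) flow steps; each step moves a per-dimension uniform fraction of
the distance toward a pool member drawn rank-biasedly
(`rank = ⌊capacity · U^rank_bias⌋`, default bias 4 — strong elitism), then
receives Gaussian jitter with per-dimension SD `scale · β_t · (dᵢ − bᵢ)`
(scale 0.1). The flow coefficient decays as `β_{t+1} = β_t (1 − t/T)` from
β₀ = 0.005, collapsing the jitter early and leaving refinement to the
contraction of flow steps.

Opposition-based learning evaluates the bound-reflected inverse point
`c'ᵢ = bᵢ + dᵢ − cᵢ` of every newly generated raindrop and keeps the
strictly fitter of the pair (ties keep the original, matching the ≥ branch
of the selection rule). A raindrop that fails to improve for more than
`max_stagnation` (10) consecutive iterations is restarted: at its inverse
point in the OBL variant, by uniform resampling in the plain-ARA ablation
(`use_obl=False`). That difference matters: uniform restarts discard the
refined positions that feed the pool late in a run, which is why plain ARA
plateaus orders of magnitude above the OBL variant on Ackley. Out-of-bounds
positions are clamped. The best-so-far trace is read off the pool head and
is non-increasing by construction.

The phases of the underlying raindrop metaheuristic (vapor/cloud dynamics)
have no canonical form; the flow-step realization above was chosen as the
simplest population dynamic consistent with the raindrop/flow/pool
vocabulary that keeps the specified mechanics (opposition selection, pool
update, β schedule, stagnation escape) load-bearing. The rank-bias exponent
was fixed at 4 after a small design sweep on scratch runs and then frozen.

Baselines for the comparison harness, with conventional settings:
DE/rand/1/bin (F = 0.5, CR = 0.9) and global-best PSO with inertia decaying
0.9 → 0.4, c₁ = c₂ = 2.0, velocity clamped to half the range. All four
algorithms run under equal *iteration* budgets with paired seeds; OBL
roughly doubles the evaluation count of OBL+ARA, and evaluation counts are
reported alongside. On even test functions with symmetric bounds (Ackley,
Rastrigin) the inverse point is −c with identical fitness, so the per-
candidate opposition step never switches there; the variants still diverge
through their different stagnation restarts.

## Hyperparameter tuning

`tune_with_ara` minimizes (1 − mean stratified 5-fold CV accuracy) over a
continuous box for (n_trees, max_depth, features_per_split), rounding
positions to integers before evaluation and memoizing repeated integer
configurations. Grid search over {50,100,150,200} trees × {10,20,30,40}
depth with shared folds (paired cells) is the reference selector; ties
prefer the smaller model (fewer trees, then shallower).

## The synthetic cohort generator

Institutional fitness records are not shareable, so experiments run on
generated stand-ins. Each cohort has `n_participants` (default 1500) rows
labelled competition / non-competition (balanced by default), with
`n_informative` (5) indicators whose class-conditional means differ by
`effect_sizes` (1.5) within-class SDs, and `n_noise` (15) class-independent
Gaussian indicators. Indicator names, baseline means and SDs come from a
fixed fitness vocabulary (height, resting heart rate, 50 m sprint time, …)
purely for readable reports; which slots carry signal is itself randomized.
Corruption is injected on demand: exactly `round(rate × n_cells)` cells
blanked, and the same count replaced by values at mean ± U(4,6)·SD of the
pre-injection column — guaranteed to trip the 3σ screen. Everything is
driven by one seed and reproduces byte-identically.

With five independent 1.5 SD effects the classes are separated by a
Mahalanobis distance of √(5·1.5²) ≈ 3.35, i.e. a Bayes error near 5%;
held-out forest accuracies of 0.85–0.95 and easy top@5 recovery are the
expected regime. The generator draws i.i.d. Gaussians: it does not model
indicator correlations, longitudinal training dynamics, heavy-tailed
measurement error, or label noise. Passing tests therefore demonstrate the
pipeline's correctness and its ability to recover planted additive effects,
not performance on real cohorts.

## Preprocessing

Missing cells are filled with their column mean first; then rows with any
cell beyond 3 SDs are dropped, with z computed against post-imputation
column statistics exactly once (no re-screening after removal). A wholly
missing column is an error.

## Numerical conventions

* Logarithms base 2; 0·log 0 := 0; class-proportion vectors validated to
  sum to 1 within 1e-8.
* Penalized objectives implemented exactly as specified: l1 `J + λ‖w‖₁`,
  l2 `J + α‖w‖₂` (the norm, not its square), and the elastic form
  `J + αλ‖w‖₁ + ((1−α)/2)·α‖w‖₂` with the repeated α factor; the
  conventional mixture is available as `variant="elastic_standard"`.
* Pearson correlation uses population moments; zero variance is an explicit
  error, not NaN.
* Vote-share and leaf-majority ties break toward the lowest class index.
* Forest and generator randomness flows from a single integer seed through
  `numpy` generators; per-tree node-subset sampling is seeded per tree.

## Problem sizes used by the test suite

Scalar-math oracles run on 1000 random inputs per operation against 50-digit
`mpmath` references. Tree equivalence is enumerated exhaustively over all
4-sample × 2-feature binary datasets plus 300 random ≤8×4 datasets. The
benchmark comparison uses 30 seeded runs × 1000 iterations on the 10-D
Ackley ([−32.768, 32.768]) and Rastrigin ([−5.12, 5.12]) functions. The
forest trend, recovery and held-out checks use 20 cohorts of 1500
participants each; the trend and held-out checks evaluate the corner cells
of the tree/depth grid ({50,200} × {20,40} and {50,200} × {10,40}) with
shared 5-fold CV, which bounds the suite's runtime while preserving the
paired comparisons of interest. `scripts/acceptance.py` repeats the
pipeline on 5 cohorts and the benchmark with 10 runs per algorithm.

## Known limitations

* The importance ranking (like all impurity-based rankings) favours
  continuous features with many split points; with an all-continuous
  vocabulary this bias is immaterial here.
* The forest handles multiclass labels through the same vote machinery but
  the pipeline's metrics are binary with an explicit positive class.
* The optimizer is derivative-free and sequential; no parallel evaluation.
* `as_printed` importance is faithful to its defining formula but is not a
  usable selection signal (see above) — it exists for study, not for use.
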