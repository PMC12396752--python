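# Methods

## The ocotillo search

The optimizer maintains a population of `N` candidate solutions and runs two
phases per iteration.

**Exploration.** Each position Θ is perturbed coordinate-wise by three
trigonometric factors evaluated on the position itself,

    D = 2·cos(Θ) / Train²          (distance factor)
    A = sin(ab·Θ)                  (amplitude, |A| ≤ 1; ab defaults to 1)
    L = 1 − 2·sin(Θ)·(1 + 8·cos(Θ))²   (learning factor)

via `Θ' = Θ + A·D + r1·L`, with `r1 ~ U(0,1)` drawn per solution per
iteration.  `Train` is by default the 1-based iteration index, so the `D`
term (and the oscillation sum below) decays like `1/t²`: wide moves early,
small corrections late.  A fixed-scalar `Train` is available by
configuration.  `L` is the dominant exploration term; its range is roughly
[−65, +1.4] over a period, which is what gives the method its large,
sign-alternating jumps.

**Exploitation.** For each solution two refinement candidates are built and
both are evaluated:

* the *Gaussian mutation* `Θ' = g + L1·r1·A_i/Train + F·A_o`, where `g` is
  drawn per coordinate from `N(µ, σ)` with µ the population mean position and
  σ = 1 by default, `L1`/`A_i` are the learning factor and amplitude of the
  current solution, `A_o` the amplitude of the global best, and
  `F = Σ_{n=0}^{10} sin(n·Θ)/Train²` an 11-term oscillation sum;
* the *alternative mutation* `Θ'' = (r2·i²)·(K·A_i/(i·Train)²)²` with `i`
  the 1-based solution index and `K = 1 − (g/(A_i + D))²` the convergence
  factor.

The fitter candidate (after bounds repair) replaces the solution — ties keep
the Gaussian candidate.  Replacement is unconditional; elitism lives solely
in the tracked best-so-far solution, which never worsens.  A third uniform
draw `r3` is declared by the method but used by no update rule; it is drawn
and discarded once per iteration (configurable) so the random stream matches
a fully literal reading of the update loop.

**Budget.** Each iteration costs `N` evaluations in exploration plus `2N` in
exploitation, so a run uses exactly `N·(1 + 3·max_iter)` evaluations.  When
comparing against random search we therefore give the random oracle each
run's own `evaluations_used`, making those comparisons exactly
budget-matched.  The five baselines consume `N·(1 + max_iter)`.

**Numerical guards.** Denominators (`Train²`, `(i·Train)²`, `A + D`) are
floored in magnitude at `division_eps = 1e-12`, sign-preserving.  Objectives
returning non-finite values are assigned `+inf` fitness and a warning is
logged.  Bounds repair is `clip` by default; `reflect` mirrors once about the
violated bound and then clamps.  Fitness ties anywhere resolve to the
first-encountered candidate (stable population order).

Why this works on the benchmark suite: the alternative mutation produces
small positive coordinates of order `1/(i·t)⁴`, which combined with elitist
tracking drives rapid convergence whenever the optimum lies near the origin
(sphere, Rastrigin, Ackley).  On shifted problems the Gaussian mutation
around the population mean carries the search; it behaves like an annealed
global sampler rather than a gradient-like descent.

## Binary variant

Feature selection searches `{0,1}^d` (bit j = feature j kept).  The same
update rules are evaluated literally on the 0/1 coordinates — so only the
values `cos(0), cos(1), sin(0), sin(1)` enter the factors — and the
real-valued update is mapped back to bits by the logistic transfer
`S(x) = 1/(1+e^{−x})` followed by stochastic thresholding
(`bit = 1` iff `S > u`, `u ~ U(0,1)` per coordinate).  No velocity or
continuous shadow position is carried; the mask is the whole state.  Both
exploitation candidates are binarized and compared by fitness.  An all-zero
mask is repaired before evaluation: the default policy sets one uniformly
random bit; a `resample` policy re-draws the binarization up to 10 times
first.  Within a run the evaluation split is fixed, so mask fitness is
memoized (`CachedSubsetFitness`); at d = 12 a run touches at most 4,095
distinct masks, which keeps full 500-iteration protocols cheap.

## Wrapper fitness

A candidate mask is scored by `f = ω·err + (1 − ω)·|mask|/d` with ω = 0.99,
where `err` is the misclassification rate of a k-nearest-neighbour
classifier (k = 5, Euclidean distance, majority vote) on the masked columns,
evaluated on a stratified 70:30 holdout split fixed by the fitness seed
(a stratified k-fold alternative is provided).  Columns are standardized
with the training fold's mean and variance so distances are
scale-comparable.  The small ω-complement makes subset size a tiebreaker:
error dominates, and among equal-error masks the smaller wins.  KNN is used
as the embedded evaluator precisely because it is non-parametric and
training-free, so the fitness landscape over masks is stable across runs.

## Baselines

PSO (c1 = c2 = 2, inertia 0.3), GWO (`a` linear 2→0), FA (step 0.94,
β0 = 1, γ = 1), GA (mutation 0.05, crossover 0.02) and WOA (spiral constant
linear 2→0) follow their canonical textbook update rules with population 30.
Two published parameter listings were internally inconsistent and are
resolved as deliberate choices here: the firefly algorithm uses the standard
attractiveness model with population 30 like every other method (the
listed "wormhole existence probability" belongs to a different optimizer,
and the firefly count of 10 appeared under the genetic algorithm), and the
genetic crossover rate of 0.02 — implausibly low but stated — is implemented
as printed and is configuration-overridable.  Binary variants route their
continuous updates through the same sigmoid/thresholding layer (binary PSO
transfers the velocity, the standard construction); the genetic algorithm
works natively on bit strings with single-point crossover and bit flips.

## Synthetic data

`make_feature_table` emulates a table of deep-feature embeddings with
planted structure: `k` informative columns, `r` redundant columns, and
pure-noise columns, `n` rows with balanced class labels.

* Class means on the informative axes follow a binary (or smallest-base)
  code of the class index: with the defaults (k = 3, c = 8 classes) axis j
  carries bit j of the class label, so each informative feature separates a
  different bipartition of the classes and no informative feature can be
  substituted by the others.  Adjacent codes differ by
  `class_separation·noise_sd` (default 4σ) on exactly one axis.  This is the
  deliberate reading of "informative" for a multi-class cytology-like
  problem: each axis captures an independent morphological contrast.
* Redundant column = its parent informative column plus Gaussian noise of
  0.7·noise_sd.  Because the class-mean spread inflates the parent's
  variance, the parent–child Pearson correlation is ≈ 0.95, yet the copy is
  measurably worse than the parent as a classifier input — so the wrapper
  fitness strictly prefers the true informative set over redundant swaps.
* Noise columns are standard Gaussian, independent of the labels.

What the generator does *not* imitate: the geometry of real embedding
manifolds, class imbalance, batch effects, or any image-level statistics.
Passing the recovery tests therefore shows that the selector finds planted,
individually necessary signal under Gaussian class-conditional noise — not
that it would isolate biologically meaningful markers in real cytology
embeddings.

`make_hpo_surface` is a deterministic stand-in for classifier validation
accuracy during tuning: `score = 1/(1 + penalty)` with a quadratic penalty
of 2.0 per squared decade of learning-rate error and 8.0 per squared unit of
dropout error, plus 0.25 per wrong categorical choice.  Its unique maximum
(exactly 1.0) is the reference configuration lr = 0.001, dropout = 0.3,
batch 64, 64 filters, 3 conv layers, Adam, ReLU.  `tiny_classifier_evaluator`
offers a stochastic alternative that actually trains a small scikit-learn
MLP on a separable synthetic table (dropout is mapped to an L2 penalty,
both ReLU variants to `relu` — scikit-learn has neither dropout nor leaky
ReLU).

## Hyperparameter decoding

Optimizers tune over the unit cube; each axis decodes independently:
log-uniform (`10^(log lo + u·(log hi − log lo))`) for the learning rate,
linear for dropout, uniform binning for categorical axes with `u = 1`
falling in the last bin.  Binning keeps decoding monotone and surjective
without one-hot axis inflation.

## Statistics

* Confusion metrics follow the standard closed forms; zero-denominator
  metrics are NaN with a warning rather than an error.  Multi-class
  predictions get per-class one-vs-rest metrics plus macro and micro
  averages, labelled as such — no attempt is made to guess which averaging a
  published single-row table used.
* Run statistics over repeated selection runs use the population (1/n)
  standard-deviation divisor, matching the defining formula they implement.
* The one-way ANOVA reports the full SS/DF/MS decomposition; all-identical
  groups yield a flagged degenerate table (F = ∞, p = 0).
* The Wilcoxon signed-rank test discards zero differences, ranks absolute
  values with mid-ranks, and computes the exact two-tailed p —
  `2·P(W ≤ min(W+, W−))` by dynamic programming over the 2^n sign
  assignments — whenever n ≤ 25 and no ties are present; otherwise it falls
  back to the normal approximation with continuity and tie correction and
  clears `exact_flag`.
* `reconstruct_confusion` brute-forces the smallest integer count table
  whose sensitivity/specificity/PPV match given targets within a tolerance;
  it exists as an oracle for checking published metric rows and for
  round-trip property tests.

## Problem sizes used in the shipped checks

The acceptance studies run at desk scale: binary-oracle equivalence at d = 8
with the full 500-iteration protocol; planted-feature recovery on the
default n = 400, d = 12 table with 100 iterations (the memoized fitness
makes longer protocols redundant — the search already touches most of the
4,095 masks); hyperparameter recovery with population 30 × 100 iterations;
dominance comparisons at d = 5 with 200 iterations and exactly matched
random-search budgets; 10 seeds everywhere.  The full study protocol
(30 runs × 500 iterations) remains available through `ExperimentConfig`
defaults.

## Known limitations

* The search has no explicit attraction toward the incumbent best in its
  exploration phase; on bounded spaces whose optimum is far from both the
  origin and the population mean it degrades toward annealed Gaussian
  sampling with elitism.
* The alternative mutation's pull toward small positive coordinates
  flatters benchmarks with origin optima; benchmark wins should be read
  with that in mind.
* Binary updates evaluate trigonometric factors on raw 0/1 coordinates, so
  the factor values take only four distinct magnitudes per term; the
  stochastic binarization supplies all remaining diversity.
* The exact Wilcoxon path requires tie-free magnitudes; tied data silently
  use the approximation (flagged in the result).
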