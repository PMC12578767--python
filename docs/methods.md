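# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `tropgrad`, in the order of the package modules.

## State space and conventions

All computations live on the tropical projective torus R^N / R**1**:
vectors modulo addition of a constant to every coordinate.  The canonical
representative of a class is the translate with coordinate sum zero
(`core.canonicalize`), and all stored points, datasets and optimizer
iterates are canonicalized on construction; every exported quantity (norms,
metrics, objective values, subgradients, optimizer traces) is invariant
under the choice of representative.  The max-plus convention (⊞ = max,
⊙ = +) is the default for hyperplanes, segments and hulls; min-plus
counterparts are obtained by global negation.

Tolerances: class equality and zero-distance tests use an absolute
tolerance of 1e-9 throughout.  The core operations are compositions of
additions, maxima and sorts of the inputs, so there is no numerical
conditioning to speak of; 1e-9 comfortably covers accumulated rounding.

Second extremes (used by the hyperplane distance) follow multiset
semantics: the second entry in sorted order, so a duplicated maximum is its
own second maximum.  This makes "distance zero" coincide exactly with
membership of the hyperplane, where the maximum is attained at least twice.

## Objectives and subgradients

Each location problem exposes a value and a *selector subgradient*: one
Clarke-subdifferential element assembled from argmax/argmin indicators with
lowest-index tie-breaking.  Analytic selectors were chosen over automatic
differentiation because they are dependency-light and make the gradient
contract provable: a strictly negative component at coordinate j occurs
only when j attains min_i (t_i − x_ki) for some sample k (for Wasserstein
projections, with the reduced points z_k in place of x_k).  The contract is
exercised on >10^4 random probes in the test suite, including a corrupted
negative control.

Details worth recording:

- The Fréchet subgradient at objective value 0 is returned as the zero
  vector (0 belongs to the Clarke set at a global minimum; the optimizer
  then terminates).
- The Wasserstein projections are treated as min-tropical location
  problems in the reduced variables z_ki = x_ki − y_kj; the per-sample
  loss h_k(t) = max_j (min_{i∈J_j} (t − z_k)_i − min_a (t − z_k)_a) is
  nonnegative by construction and the p-mean chain rule weights the
  selector of each sample by h_k^{p−1} / (K f^{p−1}).
- The Fermat–Weber optimum is computed exactly by a linear program
  (HiGHS): minimize (1/K) Σ_k (u_k − l_k) subject to
  l_k ≤ t_i − x_ki ≤ u_k, with the gauge Σ_i t_i = 0 pinning the
  representative.  For the other objectives, `reference_optimum` returns
  the best value over any candidate runs plus one long tropical-descent
  run (10× the benchmark step budget); it is monotone under refinement.

## Optimizers

Seven methods share one driver (`optim.run_optimizer`):

- **CD / SGD** — classical subgradient descent, step
  a_m = γ‖g‖₂/√m along −g/‖g‖₂ (equivalently t ← t − (γ/√m) g); SGD
  evaluates the subgradient of a single uniformly drawn sample per step.
- **TD / TSGD** — tropical descent: t ← t + a_m d with
  a_m = γ‖g‖_tr/√m and d the normalized tropical steepest descent
  direction.  Two directions are steepest in the tropical norm: the *min*
  convention raises the coordinates with negative subgradient (the
  default), the *max* convention lowers those with positive subgradient.
- **Adam / Adamax** — standard moment recursions with constant rate γ,
  β₁ = 0.9, β₂ = 0.999, ε = 1e-8.
- **TrAdamax** — Adamax-style moments of the unnormalized tropical
  direction d̃_i = −g_i·1[g_i<0] (min convention): first moment with bias
  correction, infinity moment u ← max(β₂u, d̃), update
  t ← t + γ·(m̂/u) with coordinates where u = 0 left unchanged.

Every iterate is re-canonicalized (mean subtracted) by default — raw
tropical descent is coordinate-monotone and would grow without bound —
and runs terminate early on an exactly zero subgradient.  All stochastic
draws go through a caller-supplied generator, so traces are bit-identical
under a fixed seed.

The rate calculator implements the distance-to-hull bound

    eps_m = 2√2 αN / (√(m+1) − KDL/(2α) + √(LKN−1) − √2),

valid for m ≥ max{(√2 + KDL/2α − √(LKN−1))² − 1, (2αN/D)²}, with the
one-sample variant (K = 1) bounding the distance to the global minimum of
a star-quasi-convex problem.  The D budget is estimated from a finished
run as max_m d_max(t*, t_m) with t* the mean of the final 10 iterates.
Linear regression has ‖∂f‖_tr = 2 almost everywhere, so its diagnostics
use L = 1.

### Stable points of tropical descent, and the direction convention

Tropical descent converges to the max-tropical hull of the data, but for
multi-sample problems nothing forces the hull point it parks at to be a
minimizer.  On generic data (branching or Gaussian clouds) the package's
TD routinely lands on the exact minimum cell of the piecewise-linear
objectives.  On cophenetic data of multi-species-coalescent gene trees,
however, the min-convention direction has a stable oscillation far from
the optimum (relative error 0.3–1.4 in our experiments, persisting for
100k steps and under constant-step annealing) while classical descent,
Adam and the exact LP agree on the optimum; the stall sits within 0.02 of
the hull, so the hull-convergence guarantee is intact.  Ultrametric
vectors are highly tied (28 coordinates share 7 distinct values per
sample), and the induced cell geometry destabilizes the "raise the
negative coordinates" dynamics.  The centrality statistics are both min-
and max-tropical location problems, so the mirrored max-convention
direction is equally principled — and it converges cleanly on this data.
The species-tree pipeline therefore uses `convention="max"` by default;
everything else defaults to the min convention.

## Synthetic data

The generators define the study conditions:

- **branching** — rate-1 Yule (pure-birth) topologies whose edges are then
  assigned i.i.d. Exp(1) lengths.  Clock-like pure-birth trees would be
  ultrametric and land exactly on the tropical hyperplane (making the
  regression minimum identically zero); independent edge lengths keep the
  branching datasets off that degenerate locus while preserving
  birth-process tree shapes.
- **coalescent** — Kingman coalescent (rate 1 per lineage pair, population
  size 1), always ultrametric.
- **MSC gene trees** — one lineage per species, Kingman coalescence within
  each species-tree branch, unmerged lineages passed rootward (dendropy's
  contained-coalescent simulator); gene divergences are never younger than
  the species divergences.
- **Gaussian** — i.i.d. standard normal vectors, canonicalized.

Datasets are rescaled to mean tropical norm 1 for comparability across
shapes and dimensions.  Cophenetic vectors use lexicographic leaf-pair
order, recorded as "A|B"-style headers in CSV output.  The default 8-leaf
species tree is a caterpillar with cherries, topology
(((((F,E),(H,G)),(D,C)),B),A), with consecutive divergences spaced by one
coalescent unit (configurable); branch lengths are a package choice, as
only the topology of the reference tree is fixed.

What the generators do *not* emulate: estimated gene trees carry
reconstruction error and alignment noise; real species trees have
heterogeneous population sizes and branch lengths; Exp(1) edge lengths are
a stylized departure from any specific molecular-clock violation.  Passing
tests therefore demonstrate correctness of the algorithms under the stated
models, not robustness to real-data artifacts.

The single-linkage projection returns the subdominant ultrametric — the
entrywise-largest ultrametric below the input, equal to the min-max path
closure and to the tropical projection onto ultrametric tree space.  It
commutes with adding a constant to all entries, so canonical (sum-zero)
inputs are handled by shifting into the positive range and shifting back;
the returned tree is built in the shifted gauge with node ages at half the
merge heights.  Canonical topology strings order children by smallest
descendant leaf label, making string equality a topology test.

## Benchmark protocol and error metrics

Benchmarks run every method for 1000 steps from a shared set of standard
Gaussian initializations (bit-identical across methods), with the learning
rate chosen per method by grid search (half-decade grid 10⁻³…10¹) on
tuning replicates seeded disjointly from evaluation.  Errors are measured
as natural-log errors of the final objective value against a reference
optimum — exact (LP) for Fermat–Weber, best-found for the rest, absolute
(ln f_final) when the true optimum is 0, as for regression on ultrametric
data.

Because the objectives are piecewise linear, tuned runs frequently land on
the *exact* minimum value, which makes an unfloored mean log relative
error degenerate (dominated by the clipping constant).  The centrality
benchmark therefore applies a 1% floor, reporting mean ln(rel + 0.01); a
run that exactly solves the problem contributes ln 0.01 ≈ −4.61.  The
linear-regression benchmark reports the unfloored mean (clipped at 1e-16),
which is realization-dependent whenever a nontrivial fraction of runs hits
the optimum exactly — its variance across dataset draws is large, and the
mean should be read as an order of magnitude, not a point estimate.

Problem sizes used by the shipped pipelines (10 or 100 samples in 6 or 28
dimensions, 50–100 initializations, 1000–3000 steps) were chosen to match
the study design while keeping a full reproduction run in the minutes
range on one core.

## Auction regression

For N firms and K products in price equilibrium, the preference-adjusted
winning log-price of each product is tied between two firms, which places
the columns of −p on the max-tropical hyperplane with apex log f (f the
hidden preference factors).  The generator draws a base price per product,
ties two random firms, and lifts the rest by a positive margin; optional
Gaussian noise moves the data off exact equilibrium.  Estimation is
tropical linear regression on the columns of −p followed by
f̂ = exp(t − max t), so the largest factor is normalized to 1.

## Known limitations

- Tropical descent's stable points for multi-sample problems are only
  guaranteed to lie in the tropical hull; the min/max direction choice
  matters on tied, hyperplane-supported data (see above).
- `reference_optimum` for non-Fermat–Weber objectives is a best-found
  value, not a certificate; regression references could in principle be
  computed exactly via mean-payoff-game solvers, which are out of scope.
- The Wasserstein subgradient uses one maximizing block per sample; at
  points where several blocks tie, the lowest-index choice is one Clarke
  element among many, as with all selectors here.
- Exact polytope combinatorics (vertex enumeration of tropical hulls) is
  not implemented; only membership and metric projection are provided.
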