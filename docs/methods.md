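# Methods

## Model

Gene-pair predictors are pairwise log-expression ratios. The pair model

    y_i = Σ_{j<k} α_jk (log x_ij − log x_ik) + ε_i,    ε_i ~ N(0, σ²),

with the antisymmetric convention α_kj = −α_jk, is equivalent to the
gene-level model

    y_i = Σ_j β_j log x_ij + ε_i,    Σ_j β_j = 0,    β_j = Σ_{k≠j} α_jk.

The α → β map is linear and many-to-one: adding a constant around any
cycle of pair indices (α_{i1 i2}, α_{i2 i3}, …, α_{ik i1} all shifted by
c) leaves β unchanged, so the pair parameterization is non-identifiable
while the constrained gene parameterization is identifiable and only
p-dimensional. The sum-to-zero constraint is what delivers normalization
robustness: adding a per-sample constant c_i to all log-expressions (a
per-sample rescaling of raw expression) changes predictions by
c_i · Σ_j β_j = 0.

### Minimum-L1 pair representations

Among the infinitely many α mapping to a given β we report one of minimum
L1 norm. Three equivalent characterizations of minimality are implemented
(`is_minimum_l1`): no two coefficients sharing a gene index have a
strictly positive product under the antisymmetric extension (equivalently,
at every gene all incident pair coefficients carry the same sign, so the
nonzero pattern is a bipartite graph between "source" and "sink" genes);
and the norm identity ‖α‖₁ = ‖β‖₁/2. The representation is *uniquely*
minimal (`is_unique_minimum_l1`) exactly when, additionally, all nonzero
pairs share one hub gene — equivalently the induced β has a hub j with
|β_j| = Σ_{i≠j}|β_i|. Support counts obey B ≤ 2A always, 2√A ≤ B under
minimality, and B = A + 1 under uniqueness (A = nonzero pairs, B =
nonzero genes).

### Peeling

`peel` converts a sum-to-zero β into a minimal pair set: repeatedly select
the most positive and most negative remaining coefficients (ties broken by
lowest index — one valid instantiation of an arbitrary tie-break, chosen
for determinism), assign the smaller magnitude as the pair weight, and
subtract it from both sides. Each step zeroes at least one coefficient, so
at most p − 1 pairs are produced in at most p steps; each step grows ‖α‖₁
by the transferred weight while ‖β̃‖₁ shrinks by twice that weight, giving
‖α‖₁ = ‖β‖₁/2 exactly — the minimum. Different tie-breaks can give
different, equally minimal pair sets; uniqueness holds only under the hub
condition above. Inputs whose sum deviates by more than
1e-8 · max(1, ‖β‖₁) are rejected; smaller residuals are mean-projected
away before peeling, and pair weights below 1e-12 (rounding dust near
termination) are dropped, which preserves the round-trip contract at
1e-10.

## Solver

The fit solves min ½‖Ax − b‖² + λ‖z‖₁ subject to Cx = d and x = z by
ADMM in scaled-dual form. One iteration:

    x ← (AᵀA + ρCᵀC + ρI)⁻¹ (Aᵀb + ρ(z − Cᵀu₁ + Cᵀd − u₂))
    z ← S_{λ/ρ}(x + u₂)          (soft threshold, penalized coordinates)
    u₁ ← u₁ + (Cx − d);  u₂ ← u₂ + (x − z)

with C = 1ᵀ, d = 0 for the sum-to-zero model. An unpenalized intercept is
an all-ones first column excluded from both the constraint row and the
threshold. The x-update matrix is independent of λ and factorized once
per path: a Cholesky factor of the m×m normal matrix when the design is
tall, or — when m > n + 1 — the matrix inversion lemma on the
(n+1)×(n+1) Gram of the stacked rows [A; √ρ C], so wide pair designs cost
O(n·m) per iteration. Stopping uses the standard primal/dual residual
criteria with absolute and relative parts (defaults ε_abs = 1e-6,
ε_rel = 1e-4); non-convergence within max_iter (default 100 000) is
reported with a warning, never silently accepted.

Parameters that matter:

* **ρ = 1.0** (augmented-Lagrangian penalty, dimensionless). Fixed;
  results at tight tolerances are insensitive to it, and it is exposed in
  `ADMMConfig` for the curious.
* **λ grid** — geometric, user-supplied or 100 points from
  λ_max = ‖Aᵀb‖∞ (response centered when an intercept is present) down to
  0.01·λ_max, warm-started downward. At λ ≥ λ_max all penalized
  coefficients are zero.
* **Cold-start duals** — a cold start initializes the scaled dual at
  u₂ = clip(Aᵀb, ±λ)/ρ, which is exactly the KKT dual of the all-zero
  solution for λ ≥ λ_max; without it the dual must accumulate to ~λ/ρ at
  O(1) per iteration, which is slow for the large first grid points.
* **Reported coefficients** — the split variable z (exactly sparse).
  Downstream consumers that require exact feasibility (peeling, the
  convergence benchmark) use its exact sum-zero projection; at
  convergence the projection is of the order of the primal residual.

No predictor standardization is applied by default (an optional concern
left to the caller); simulations are fit without an intercept (their
generative model is mean-zero with no intercept term), the RNA-Seq
pipeline with one.

### Independent reference solver

`pairzero.oracle` provides the ground truth the solver is benchmarked
against: accelerated proximal gradient (FISTA with adaptive restart)
whose prox step handles the L1 term and the sum-to-zero constraint
jointly and exactly — S_t(v − μ1) with μ the bisection root of the
monotone map μ ↦ Σ S_t(v − μ). For the benchmark sizes (n ≥ p) the
objective is strongly convex on the constraint set, the iteration
converges linearly, and solutions are accurate to ~1e-13; two runs at
different tolerances agree to 1e-14, an order of magnitude below
everything compared against them. A linear program (HiGHS) over split
positive/negative pair weights independently certifies the minimality of
peeled representations on small p.

## Synthetic data

Log-expressions are drawn iid across samples from N(0, V) with
V_ij = 0.5^|i−j| (AR(1), locally correlated genes); responses follow the
gene-level model with iid Gaussian noise. Three fixed sparse settings
probe the minimality conditions (indices 1-based): α₁₂ = 1, α₁₃ = 0.5
plus α₂₄ = 0.5 (not minimal), α₂₄ = −0.5 (minimal, not unique), or
α₁₄ = 0.5 (uniquely minimal star with hub gene 1), inducing
β = (1.5, −0.5, −0.5, −0.5), (1.5, −1.5, −0.5, 0.5) and (2, −1, −0.5,
−0.5) respectively. A fourth generator draws a dense centered-N(0,1) β
with N(0,1) noise for solver benchmarks. Robustness transforms: iid
N(0,1) per-sample additive shifts in log space, and per-sample/per-gene
multiplicative log-normal(0,1) factors on raw expression (any positive
law would exercise the same invariance).

What the generator does *not* emulate: count noise, zero inflation,
gene-length effects, heteroscedastic library sizes and outlier samples of
real RNA-Seq. Passing benchmarks therefore demonstrate correctness of the
estimator and its normalization invariances under the stated generative
model, not performance on real data.

## Benchmarks

**Convergence.** For (p, n) ∈ {(20,50), (100,100), (100,500),
(200,1000)}, 20 replicates each at λ = 1: ADMM run so that its residual
norms reach 1e-10 (ε_abs = 1e-10/√(p+1), negligible relative part — the
scaled-criterion defaults would stop at residuals ~√p·1e-10, which at
the ill-conditioned p = n size maps to solution errors above the success
cut). Success requires the raw solution to satisfy the constraint within
1e-8 and the reported (projected) solution and its objective to lie
within 1e-8 of the FISTA reference. Reported as a percentage; wall-clock
times are informational only.

**Accuracy.** For each coefficient setting and (p, n, σ) ∈ {(20, 50,
0.5), (100, 25, 0.2)}: fit on n training points over the fixed grid of
100 λs from 1e4 to 1e-2; select λ by MSE on an independent 1000-point
test set; evaluate MSE and R² = 1 − MSE/var(y) on an independent
1000-point validation set whose *predictors* receive N(0,1) per-sample
shifts (the shift emulates a normalization change of expression, so the
response is left untouched); score coefficient recovery by relative
error ‖γ̂ − γ⁰‖₂/‖γ⁰‖₂ and by the false identification rate
1 − |Γ̂ ∩ Γ⁰|/|Γ⁰|, where Γ̂ keeps the |Γ⁰| largest-magnitude estimates
(ties by lowest index). The constrained fit and the unconstrained
gene-level lasso are scored against the true β; the pair-design lasso
against the true α. The two unconstrained baselines are fit with
coordinate-descent lasso (scikit-learn) on the matching designs — a
standard computation, with the package's own `unconstrained_fit`
cross-checked against it in the tests. Twenty replicates per cell; means
and standard errors over replicates; replicates with any non-converged
path fit are excluded with a warning.

## RNA-Seq pipeline

Genes × samples non-negative expression (TSV; genes as rows, the
bioinformatics convention) plus a positive per-sample response. Steps:
drop genes with mean expression strictly below 10 (the conventional
low-abundance cutoff for normalized RSEM estimates); Pearson correlation
of log-expression against log-response per gene, two-sided p-values from
the exact t transform with n − 2 degrees of freedom, Benjamini–Hochberg
adjustment across all testable genes, retain FDR ≤ 0.01; fit the
constrained path on the retained log-expressions with an unpenalized
intercept; peel every grid point into its minimal pair set and report
genes by order of first entry.

Numerical and design choices: zeros in expression raise an error unless
an explicit pseudocount is supplied (default 1 when enabled) — the
abundance filter makes zeros rare but not impossible; constant genes have
no defined correlation and are excluded with a recorded reason; the
default grid anchor λ_max is computed on the *row-centered* log design,
which still forces the all-zero solution (feasible coefficients cannot
see a per-sample constant) while making the default grid — and hence the
whole pipeline — invariant to per-sample rescaling; the peeling input at
each λ is the coefficient vector restricted to its active support and
re-balanced there (a global projection would smear rounding dust over all
genes and create spurious hair-thin pairs); the entry threshold defaults
to 100 × ε_abs (at least 1e-10) so entry decisions sit above solver noise
and are reproducible across numerically equivalent runs. "Nonzero" for
the proposition checkers on fitted coefficients means |value| > 1e-10,
configurable.

## Problem sizes in the shipped benchmarks

The test suite runs the convergence study at the four sizes above with 20
replicates, and the accuracy study at all six (setting × size) cells with
20 replicates — the full protocol sizes. Unit and pipeline tests use
smaller instances (p ≤ 30, n ≤ 100, grids of 30–100 points) chosen to
exercise every code path at interactive speed.

## Known limitations

* ADMM with fixed ρ has a linear rate; very ill-conditioned designs may
  need many iterations at small λ (no inexact or adaptive-ρ variants).
* The minimum-L1 pair representation need not be unique off the star
  case; the reported pair set then depends on the (deterministic)
  tie-break, though its L1 norm does not.
* Minimum-L0 pair representations are out of scope.
* Generalized linear responses, grouped penalties and per-coefficient
  penalty weights are not implemented; per-column penalty flags provide
  the natural hook.
* The screening step treats genes independently; no attempt is made to
  control for correlation between screened genes.
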