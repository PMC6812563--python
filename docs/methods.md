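# Methods

## The proximal distance principle

A constrained problem `min f(x), x ∈ C = ∩ᵢ Cᵢ` is relaxed to the penalized
loss

    h_ρ(x) = f(x) + (ρ/2) Σᵢ αᵢ dist(x, Cᵢ)²,     αᵢ ≥ 0, Σαᵢ = 1,

whose minimizer tracks the constrained solution as ρ grows (with an O(1/ρ)
error in the objective for well-behaved problems).  The squared distance is
majorized at the current iterate by `‖x − P_Cᵢ(x_k)‖²`, so each iteration
minimizes the surrogate

    g_ρ(x | x_k) = f(x) + (ρ/2) ‖x − Σᵢ αᵢ P_Cᵢ(x_k)‖²,

i.e. applies a proximal map (or an equivalent structured linear solve) at the
convex combination of projections.  The MM sandwich inequality guarantees
`h_ρ(x_{k+1}) ≤ h_ρ(x_k)` at fixed ρ.  When every `Cᵢ` is convex the
iteration is a proximal gradient method (the penalty gradient is
`x − P_C(x)` wherever the projection is single valued) and obeys the
sublinear bound `h_ρ(x_{k+1}) − h_ρ(z*) ≤ ρ‖z* − x₀‖²/(2(k+1))`, which the
tests verify on projection toys.  For nonconvex sets (sparsity, sphere ∩
orthant, complementarity) the same iteration is a descent method whose limit
points are critical; multistart is then the appropriate safeguard.

The default weighting is neutral, `αᵢ = 1/m`.  Where possible a constraint
is *folded into the domain* of the loss instead of penalized — the affine
set in the first linear-programming variant, the PSD cone in the kinship
PD3 variant, the Stiefel manifold in sparse PCA — which both removes a
penalty term and makes every iterate exactly feasible for that constraint.

## Penalty schedules and convergence

ρ follows the geometric schedule `ρ_k = min(cap, ρ₀·g^⌊k/period⌋)`.  The
per-solver defaults are the tunings that work in practice for each problem
class:

| solver | dense default | sparse default |
| --- | --- | --- |
| linear programming | ρ₀ = 1, ×2 / 100 it | ρ₀ = 1, ×1.5 / 50 it |
| simplex least squares | ρ₀ = 1, ×1.5 / 200 it | same |
| kinship PD1 | ρ_k = min(1.2^k, 2²²) | — |
| kinship PD2/PD3 | ρ₀ = 1, ×5 / 100 it | — |
| SOC projection | ρ₀ = 1, ×2 / 100 it | ρ₀ = 0.01, ×2.5 / 10 it |
| copositivity | ρ_k = min(1.2^k, 2²²) | — |
| LCP | ρ₀ = 1, ×2 / 100 it | — |
| sparse PCA | ρ₀ = 1, ×2 / 100 it | — |

ρ is capped (default 2²²) rather than driven to infinity: beyond the cap the
penalty error is far below the convergence tolerances while ill-conditioning
and roundoff would only grow.  The LCP and SPCA schedules are this package's
own defaults (chosen to match the dense linear-programming tuning); both are
user-overridable.

Convergence is declared when both

    |f(x_k) − f(x_{k−1})| ≤ ε₁ (|f(x_{k−1})| + 1)    and    dist(x_k, C) ≤ ε₂

hold, with defaults ε₁ = 1e−6, ε₂ = 1e−4.  Two robustness details:
the test is skipped at iterations where ρ just increased (the loss jumps
there for schedule reasons, not convergence reasons), and the criteria must
hold at two consecutive eligible iterations — immediately after a momentum
reset a single tiny step can mimic stagnation.  With multiple penalized
sets the reported constraint distance is the maximum of the per-set
distances (conservative relative to any weighted average).

## Acceleration

Nesterov extrapolation shifts the anchor to
`z_k = x_k + (k−1)/(k+d−1)(x_k − x_{k−1})` with d = 3 and applies the
algorithm map at `z_k`.  Because the extrapolation sequence assumes a fixed
objective, the counter and memory reset whenever ρ increases; acceleration
therefore operates on the fixed-ρ subproblems.  The shift is an affine
combination, so affine constraints satisfied by consecutive iterates are
preserved exactly.  Acceleration is on by default everywhere except the
copositivity solver, where the problem is nonconvex, the gain is marginal,
and occasional non-monotone behavior makes the unaccelerated run the safer
default.

## Projection operators

All operators return a single deterministic representative; magnitude and
argmax ties break toward the lowest index so traces are bit-reproducible.
Specific choices:

* **affine**: `x − A⁻(Ax − b)` with `A⁻ = Aᵗ(AAᵗ)⁻¹` built once from an
  economy SVD (cutoff `max(m,n)·eps·σ_max`) and cached; rank-deficient `A`
  is rejected unless truncation is explicitly allowed.
* **simplex**: exact sort-and-threshold algorithm, O(n log n).
* **PSD**: symmetrize as `(X + Xᵗ)/2`, then truncate negative eigenvalues.
* **Lorentz cone**: the standard three-case formula (inside; polar cone →
  apex; otherwise radial blend `((r + ‖w‖)/2)(w/‖w‖, 1)`).
* **sphere ∩ orthant**: clamp negatives and normalize when any component is
  positive; otherwise the coordinate vector of the largest (least negative)
  component; the origin maps to e₁.
* **complementarity**: componentwise three-candidate rule; exact ties take
  the `(u_i, 0)` branch.
* **sparsity**: keep the r largest magnitudes per column or matrix-wide
  (stable sort).
* **Stiefel**: `VWᵗ` from the thin SVD; rank deficiency is completed from
  the SVD basis with a warning.
* **graph manifold** `{(x, Ax)}`: `(I + AᵗA)⁻¹(Aᵗv + u)`, routed through the
  Woodbury identity when the n×p matrix has n < p.
* **convex inequality `a(x) ≤ t`**: bracket the multiplier by doubling, then
  bisect on `a(prox_{λa}(y)) = t`, using that the left side decreases in λ.

## Solver-specific steps

* **LP.**  Variant 1 keeps `Ax = b` in the domain
  (`x_{k+1} = y_k − v/ρ − A⁻(Ay_k − b − Av/ρ)` for `y_k` the orthant
  projection); variant 2 keeps the orthant
  (`x_{k+1,j} = max(p_{kj} − v_j/ρ, 0)` for `p_k` the affine projection).
  Sparse matrices use LSQR minimum-norm solves instead of a cached
  pseudo-inverse.  After convergence a *crossover* polish snaps the iterate
  to the best feasible vertex among the m-subsets of its m+3 largest
  components, kept only if it does not worsen the cost: near the cap the
  inner steps scale like 1/ρ, so on ill-conditioned instances the penalized
  iterate can freeze a little short of the vertex it has already identified.
  Runs whose loss falls below −1e12 are flagged unbounded-suspect.
* **Simplex least squares.**  The surrogate is the stacked system
  `‖(A; √ρ I)x − (y; √ρ s_k)‖²`; dense instances reuse one spectral
  factorization of `AᵗA` across all ρ, sparse ones run LSQR on the stacked
  matrix (tolerance 1e−10, cap 4·max(m,n) iterations — inner accuracy must
  exceed the outer ε₁).  The returned solution is the simplex projection of
  the final iterate.
* **SOC projection.**  Parameter splitting adds `w = Au + b`, `r = cᵗu + d`;
  the u-update solves `(ρ⁻¹I + AᵗA + ccᵗ)u = ρ⁻¹x + Aᵗ(w̃ − b) + (r̃ − d)c`
  via the cached spectral decomposition of `AᵗA + ccᵗ` (dense) or conjugate
  gradients on the implicit operator (sparse, never forming `AᵗA`).
* **Kinship.**  PD1 penalizes the PSD cone and the structural set (diagonal
  ½, nonnegative off-diagonals) with weights ½ each; PD2 accelerates PD1;
  PD3 folds the PSD cone into the domain so each step is one spectral
  truncation of `(Y + ρP(X_k))/(1 + ρ)`.  Dykstra's alternating projections
  (standard correction-variable form) provide the convex-intersection
  reference.  After convergence the iterate is polished by alternating
  PSD/structural projections — structural last, so the output is exactly
  structural-feasible — until the residual PSD violation is below 1e−6 (it
  halves per round); pre- and post-polish losses are both reported.
* **Copositivity.**  `x_{k+1} = (M + ρI)⁻¹ ρ P_S(x_k)` via the cached
  spectral decomposition of M, with the effective penalty floored at
  `1.1·max(0, −λ_min(M))` so the shifted matrix stays positive definite.
  Ten multistarts by default: the coordinate vector of the smallest diagonal
  entry first (coordinate vectors are feasible, so the reported index never
  exceeds min_i M_ii), then uniform-simplex draws renormalized to the
  sphere.  The reported index is the quadratic form at the
  feasibility-projected best minimizer.
* **LCP.**  `x`-update `[(1+ρ)I + AᵗA]⁻¹[Aᵗ(ỹ − b) + (1+ρ)x̃]` with the
  spectral cache, `y`-update by convex blend.  The constraint set is
  nonconvex, and single-start runs stall in local minima on a sizable
  fraction of random instances, so the solver is multistart: the
  deterministic start (0, b) plus up to 19 seeded nonnegative random starts,
  stopping early at numerically zero loss.
* **Sparse PCA.**  Stiefel constraint in the domain, sparsity in the
  penalty: `U_{k+1} = P_Stiefel[S U_k + ρ P_sparsity(U_k)]`, one thin SVD
  per iteration, monotone in the penalized objective because S is PSD.
  Initialization is the top-q eigenbasis of S; when leading eigenvalues are
  close that basis is an arbitrary rotation of the sparse directions, so the
  solver multistarts over seeded Haar-random q×q rotations of it and keeps
  the best final objective.  In matrix mode with an evenly divisible budget
  the column-mode solution (always matrix-feasible) is added to the
  candidate pool, so the freer budget never scores below the restricted
  one.  The final polish alternates sparsity/Stiefel projections until the
  sparsification is a no-op (ending on sparsity, so the budget holds
  exactly and orthonormality to roundoff), then fixes signs so each
  column's largest-magnitude entry is positive.  PVE is
  `tr(X_qᵗX_q)/tr(XᵗX)` with `X_q = XU(UᵗU)⁻¹Uᵗ`, which reduces to
  `tr(UᵗXᵗXU)/tr(XᵗX)` for orthonormal loadings.

## Synthetic data

The generators are pure functions of their parameters and seed and emulate
the random-instance constructions the solvers are designed around:

* **LP**: standard-normal `A` (dense, or sparse at a given density);
  feasibility planted via `b = Ax₀` with `x₀ = |N(0,1)|`; boundedness via
  the dual certificate `v = Aᵗu + s`, `s = |N(0,1)| ≥ 0`.
* **least squares**: standard-normal `A` and `y`; sparse density 10/p.
* **kinship candidates**: standard-normal square matrices symmetrized by
  averaging opposing off-diagonal entries (off-diagonals N(0, ½)).
* **SOC**: standard-normal `A, b, c, x` with `d = ‖b‖ + |N(0,1)|`, making
  u = 0 strictly feasible by construction (a constructive version of
  resampling until the cone is nonempty).
* **LCP**: a complementary nonnegative pair `(x*, y*)` with random support
  is planted and `b = y* − Ax*`, so a zero-loss solution exists.
* **Horn matrices**: the circulant ±1 cyclic-adjacency pattern; n = 5 is
  the classical copositive matrix with variational index 0.  Even n follows
  the same pattern but carries no copositivity guarantee.
* **spiked SPCA model**: q orthonormal r-sparse loading columns on disjoint
  index blocks, scores N(0, signal²) with default signal = 5, noise
  N(0, 1); the data matrix is returned column-centered.  Equal spike
  strengths are deliberately kept: they create the rotation ambiguity that
  makes sparse recovery non-trivial.

What the generators do **not** emulate: heavy tails, correlated noise,
missingness, LD structure in real GRMs, or unequal spike strengths.  Tests
passing on these instances show the algorithms solve the stated optimization
problems under the stated randomness, not that the estimators are robust on
messy real data.

## Problem sizes used in tests and the acceptance script

Oracle comparisons run where exhaustive references are exact and fast:
LPs with m ≤ 4, n ≤ 10 against vertex enumeration; simplex least squares at
8×4 against active-set enumeration; SOC at dimension ≤ 6 against an SLSQP
conic oracle; LCPs at n = 8 against the planted optimum; kinship at 32×32
against Dykstra; the spiked SPCA model at n = 200, p = 50, q = 2, r = 10
over 20 replicates.  The acceptance script works entirely on the 5×5 Horn
matrix (10 multistarts for the index; 20 seeded single starts for the
iteration budget).

## Known limitations

* The penalty method delivers moderate accuracy by design; the reported
  optima are accurate to roughly the convergence tolerances, and the LP
  crossover/kinship/SPCA polishes exist precisely to hand back exactly
  feasible points.
* Nonconvex solvers (copositivity, LCP, SPCA) guarantee only critical
  points; multistart reduces but cannot eliminate the risk of a suboptimal
  basin.
* The kinship diagonal is fixed at ½ (no inbreeding adjustment); the solver
  exposes no per-individual diagonal targets.
* The gradient-descent and quadratic-approximation variants of the update,
  and the Lipschitz-constant-based step of the accelerated proximal
  gradient, are out of scope: no solver here requires them.
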