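"""Proximal distance solvers whose MM step is a linear-algebra solve.

Four problem classes share the pattern "project, then solve a structured
linear system":

* linear programming, with either the affine equalities (PD1) or the
  nonnegativity constraints (PD2) folded into the domain of the loss;
* least squares over the probability simplex, via a stacked ridge system;
* projection of a point onto a second-order-cone constraint
  ``{u : ‖Au + b‖ ≤ cᵗu + d}`` through parameter splitting onto the
  Lorentz cone;
* the linear complementarity problem ``x, y ≥ 0, y = Ax + b, xᵗy = 0``.

Dense instances cache one spectral factorization and reuse it across all
penalty values; sparse instances go through LSQR/CG and never form Gram
matrices explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, eigh, qr, solve_triangular
from scipy.sparse.linalg import LinearOperator, cg, lsqr

from .engine import ConvergenceSpec, PenaltySchedule, ProximalDistanceProblem, SolveResult, run
from .projections import (
    AffineProjector,
    ProjectionOperator,
    nonnegative_operator,
    project_lorentz,
    project_complementarity,
    project_nonnegative,
    simplex_operator,
)

__all__ = [
    "LPInstance",
    "SimplexLSInstance",
    "SOCInstance",
    "LCPInstance",
    "lp_step_affine_domain",
    "lp_step_nonneg_domain",
    "solve_lp",
    "solve_simplex_ls",
    "solve_soc_projection",
    "solve_lcp",
    "linear_backend",
    "LP_DENSE_SCHEDULE",
    "LP_SPARSE_SCHEDULE",
    "SIMPLEX_LS_SCHEDULE",
    "SOC_DENSE_SCHEDULE",
    "SOC_SPARSE_SCHEDULE",
    "LCP_SCHEDULE",
]

# Per-problem default penalty schedules.
LP_DENSE_SCHEDULE = PenaltySchedule(1.0, 2.0, 100)
LP_SPARSE_SCHEDULE = PenaltySchedule(1.0, 1.5, 50)
SIMPLEX_LS_SCHEDULE = PenaltySchedule(1.0, 1.5, 200)
SOC_DENSE_SCHEDULE = PenaltySchedule(1.0, 2.0, 100)
SOC_SPARSE_SCHEDULE = PenaltySchedule(0.01, 2.5, 10)
LCP_SCHEDULE = PenaltySchedule(1.0, 2.0, 100)

_LSQ_TOL = 1e-10  # inner solves must be more accurate than the outer eps_loss


def _is_sparse(A) -> bool:
    return sp.issparse(A)


# ---------------------------------------------------------------------------
# Instance containers
# ---------------------------------------------------------------------------


@dataclass
class LPInstance:
    """``min vᵗx  s.t.  Ax = b, x ≥ 0``; A may be dense or scipy.sparse."""

    A: object
    b: np.ndarray
    v: np.ndarray


@dataclass
class SimplexLSInstance:
    """``min ½‖y − Ax‖²  s.t.  x on the probability simplex``."""

    A: object
    y: np.ndarray


@dataclass
class SOCInstance:
    """Project ``x`` onto ``{u : ‖Au + b‖ ≤ cᵗu + d}``."""

    A: object
    b: np.ndarray
    c: np.ndarray
    d: float
    x: np.ndarray


@dataclass
class LCPInstance:
    """Find ``x, y ≥ 0`` with ``y = Ax + b`` and ``xᵗy = 0``."""

    A: np.ndarray
    b: np.ndarray


# ---------------------------------------------------------------------------
# Linear-system backends
# ---------------------------------------------------------------------------


class _SpectralSolver:
    """Cached eigendecomposition of a symmetric matrix B.

    ``solve(rhs, shift)`` returns ``(B + shift·I)⁻¹ rhs`` as two matrix-vector
    products, so shifted systems for every penalty value reuse one
    factorization.
    """

    def __init__(self, B: np.ndarray):
        B = np.asarray(B, dtype=float)
        self.d, self.V = eigh(0.5 * (B + B.T))

    def solve(self, rhs: np.ndarray, shift: float = 0.0) -> np.ndarray:
        coeff = self.V.T @ rhs
        return self.V @ (coeff / (self.d + shift))


class _CholeskySolver:
    """Cached Cholesky factorization of a fixed SPD matrix."""

    def __init__(self, M: np.ndarray):
        self._fallback = None
        try:
            self._factor = cho_factor(np.asarray(M, dtype=float))
        except np.linalg.LinAlgError:
            warnings.warn(
                "Cholesky factorization failed; falling back to an iterative solve",
                RuntimeWarning,
                stacklevel=2,
            )
            self._factor = None
            self._fallback = np.asarray(M, dtype=float)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        if self._factor is not None:
            return cho_solve(self._factor, rhs)
        sol = lsqr(self._fallback, rhs, atol=_LSQ_TOL, btol=_LSQ_TOL)[0]
        return sol


class _QRSolver:
    """Least squares ``min ‖Ex − g‖`` through a cached thin QR of E."""

    def __init__(self, E: np.ndarray):
        E = np.asarray(E, dtype=float)
        self.Q, self.R = qr(E, mode="economic")

    def solve(self, g: np.ndarray) -> np.ndarray:
        return solve_triangular(self.R, self.Q.T @ g)


class _IterativeLSQSolver:
    """LSQR on ``min ‖Ex − g‖`` without ever forming EᵗE."""

    def __init__(self, E):
        self.E = E
        m, n = E.shape
        self.iter_lim = 4 * max(m, n)

    def solve(self, g: np.ndarray) -> np.ndarray:
        return lsqr(self.E, g, atol=_LSQ_TOL, btol=_LSQ_TOL, iter_lim=self.iter_lim)[0]


def linear_backend(kind: str, matrix):
    """Build a reusable solver handle for one of the four system strategies.

    ``cached_spectral`` expects a symmetric matrix and solves shifted systems
    ``(B + ρI)x = rhs``; ``cholesky`` a fixed SPD matrix; ``qr`` and
    ``iterative_lsq`` a (possibly stacked, possibly sparse) least-squares
    matrix.
    """
    if kind == "cached_spectral":
        return _SpectralSolver(matrix)
    if kind == "cholesky":
        return _CholeskySolver(matrix)
    if kind == "qr":
        return _QRSolver(matrix)
    if kind == "iterative_lsq":
        return _IterativeLSQSolver(matrix)
    raise ValueError(f"unknown backend kind {kind!r}")


def _minimum_norm_solution(A, z: np.ndarray) -> np.ndarray:
    """``A⁻z`` with ``A⁻ = Aᵗ(AAᵗ)⁻¹`` for sparse A, via LSQR."""
    return lsqr(A, z, atol=_LSQ_TOL, btol=_LSQ_TOL, iter_lim=4 * max(A.shape))[0]


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------


def lp_step_affine_domain(
    yk: np.ndarray, inst: LPInstance, rho: float, pinv_cache: AffineProjector | None = None
) -> np.ndarray:
    """MM update with the equalities in the domain: stays on ``Ax = b``.

    ``x_{k+1} = y_k − v/ρ − A⁻(A y_k − b − A v/ρ)`` where ``y_k`` is the
    orthant projection of the anchor.
    """
    v = inst.v
    shifted = yk - v / rho
    if pinv_cache is not None:
        return shifted - pinv_cache.pinv_apply(inst.A @ shifted - inst.b)
    return shifted - _minimum_norm_solution(inst.A, inst.A @ shifted - inst.b)


def lp_step_nonneg_domain(pk: np.ndarray, v: np.ndarray, rho: float) -> np.ndarray:
    """MM update with the orthant in the domain: componentwise
    ``max(p_kj − v_j/ρ, 0)`` for ``p_k`` the affine projection of the anchor."""
    return np.maximum(pk - v / rho, 0.0)


def _vertex_crossover(A, b: np.ndarray, x: np.ndarray, v: np.ndarray) -> np.ndarray | None:
    """Snap a near-feasible iterate to a nearby basic feasible point (the
    crossover step of barrier LP solvers).

    Candidate bases are the m-subsets of the iterate's m+3 largest
    components — a local search around the support the penalized iterate
    identified.  Returns the feasible candidate vertex with the lowest cost,
    or None when none exists; the caller keeps the penalized iterate unless
    the vertex is at least as good.
    """
    import itertools

    m, n = A.shape
    if m > n:
        return None
    Ad = A.toarray() if _is_sparse(A) else np.asarray(A, dtype=float)
    top = np.argsort(-x)[: min(n, m + 3)]
    best_val, best_x = np.inf, None
    for cols in itertools.combinations(sorted(top), m):
        cols = list(cols)
        try:
            xb = np.linalg.solve(Ad[:, cols], b)
        except np.linalg.LinAlgError:
            continue
        if np.min(xb) < -1e-8:
            continue
        xv = np.zeros(n)
        xv[cols] = np.maximum(xb, 0.0)
        val = float(v @ xv)
        if val < best_val:
            best_val, best_x = val, xv
    return best_x


def _affine_operator_for(inst: LPInstance):
    """Affine projection operator plus the pinv cache (dense only)."""
    if _is_sparse(inst.A):
        A, b = inst.A, inst.b

        def apply(x):
            return x - _minimum_norm_solution(A, A @ x - b)

        return ProjectionOperator("affine", apply), None
    cache = AffineProjector(np.asarray(inst.A, dtype=float), inst.b)
    return cache.as_operator(), cache


def solve_lp(
    inst: LPInstance,
    variant: str = "affine_domain",
    schedule: PenaltySchedule | None = None,
    conv: ConvergenceSpec | None = None,
    accelerate: bool = True,
    backend: str | None = None,
) -> SolveResult:
    """Linear program ``min vᵗx, Ax = b, x ≥ 0`` by proximal distance MM.

    ``variant="affine_domain"`` (PD1) keeps every iterate on the equality set
    and penalizes distance to the orthant; ``variant="nonneg_domain"`` (PD2)
    does the reverse.  Defaults follow the dense/sparse tuning schedules
    (ρ₀ = 1 doubled every 100 iterations dense; ×1.5 every 50 sparse).
    """
    sparse = _is_sparse(inst.A)
    schedule = schedule or (LP_SPARSE_SCHEDULE if sparse else LP_DENSE_SCHEDULE)
    conv = conv or ConvergenceSpec()
    v = np.asarray(inst.v, dtype=float)
    affine_op, cache = _affine_operator_for(inst)

    def loss(x):
        return float(v @ x)

    if sparse:
        x0 = _minimum_norm_solution(inst.A, inst.b)
    else:
        x0 = cache.pinv_apply(inst.b)

    if variant == "affine_domain":
        def step(y, rho, anchor):
            return lp_step_affine_domain(y, inst, rho, cache)

        problem = ProximalDistanceProblem(
            loss=loss, step=step, projections=[nonnegative_operator], x0=x0
        )
    elif variant == "nonneg_domain":
        def step(p, rho, anchor):
            return lp_step_nonneg_domain(p, v, rho)

        problem = ProximalDistanceProblem(
            loss=loss, step=step, projections=[affine_op], x0=project_nonnegative(x0)
        )
    else:
        raise ValueError(f"unknown LP variant {variant!r}")

    result = run(problem, schedule, conv, accelerate=accelerate)
    x = result.solution
    xv = _vertex_crossover(inst.A, inst.b, np.maximum(x, 0.0), v)
    if xv is not None and float(v @ xv) <= float(v @ x) + 1e-6 * (1.0 + abs(float(v @ x))):
        # exactly feasible vertex at least as good as the iterate: report it
        result.extras["objective_prepolish"] = float(v @ x)
        x = xv
        result.solution = x
        result.loss_value = float(v @ x)
    result.extras["objective"] = float(v @ x)
    result.extras["affine_residual"] = float(np.linalg.norm(inst.A @ x - inst.b))
    result.extras["min_component"] = float(np.min(x))
    if result.message.startswith("unbounded"):
        result.extras["unbounded_suspect"] = True
    return result


# ---------------------------------------------------------------------------
# Simplex-constrained least squares
# ---------------------------------------------------------------------------


def solve_simplex_ls(
    inst: SimplexLSInstance,
    schedule: PenaltySchedule | None = None,
    conv: ConvergenceSpec | None = None,
    accelerate: bool = True,
    backend: str | None = None,
) -> SolveResult:
    """Least squares over the probability simplex.

    Each MM step minimizes the stacked criterion
    ``‖(A; √ρ·I)x − (y; √ρ·P_Δ(x_k))‖²`` — dense instances through a cached
    spectral factorization of AᵗA, sparse ones through LSQR on the stacked
    matrix.  Default schedule: ρ₀ = 1, ×1.5 every 200 iterations.
    """
    sparse = _is_sparse(inst.A)
    schedule = schedule or SIMPLEX_LS_SCHEDULE
    conv = conv or ConvergenceSpec(max_iter=20000)
    A, y = inst.A, np.asarray(inst.y, dtype=float)
    n, p = A.shape

    def loss(x):
        return 0.5 * float(np.sum((y - A @ x) ** 2))

    if sparse or backend == "iterative_lsq":
        def step(s, rho, anchor):
            root = np.sqrt(rho)
            E = sp.vstack([sp.csr_matrix(A), root * sp.identity(p, format="csr")])
            g = np.concatenate([y, root * s])
            return _IterativeLSQSolver(E).solve(g)
    else:
        gram = linear_backend("cached_spectral", np.asarray(A, dtype=float).T @ A)
        Aty = np.asarray(A, dtype=float).T @ y

        def step(s, rho, anchor):
            return gram.solve(Aty + rho * s, shift=rho)

    if sparse:
        x0 = lsqr(A, y, atol=_LSQ_TOL, btol=_LSQ_TOL)[0]
    else:
        x0 = np.linalg.lstsq(np.asarray(A, dtype=float), y, rcond=None)[0]

    problem = ProximalDistanceProblem(
        loss=loss, step=step, projections=[simplex_operator], x0=x0
    )
    result = run(problem, schedule, conv, accelerate=accelerate)
    # final polish: land exactly on the simplex, report the loss there
    from .projections import project_simplex

    result.extras["loss_prepolish"] = result.loss_value
    result.solution = project_simplex(result.solution)
    result.loss_value = loss(result.solution)
    result.extras["objective"] = result.loss_value
    result.extras["simplex_gap"] = float(abs(np.sum(result.solution) - 1.0))
    return result


# ---------------------------------------------------------------------------
# Second-order-cone projection
# ---------------------------------------------------------------------------


def solve_soc_projection(
    inst: SOCInstance,
    schedule: PenaltySchedule | None = None,
    conv: ConvergenceSpec | None = None,
    accelerate: bool = True,
    backend: str | None = None,
) -> SolveResult:
    """Project ``inst.x`` onto ``{u : ‖Au + b‖ ≤ cᵗu + d}``.

    Parameter splitting introduces ``w = Au + b`` and ``r = cᵗu + d``; the
    split state ``(u, w, r)`` is penalized toward the Lorentz cone
    ``‖w‖ ≤ r`` while the affine links hold exactly by construction.  The MM
    update solves ``(ρ⁻¹I + AᵗA + ccᵗ)u = ρ⁻¹x + Aᵗ(w̃ − b) + (r̃ − d)c``.
    """
    sparse = _is_sparse(inst.A)
    schedule = schedule or (SOC_SPARSE_SCHEDULE if sparse else SOC_DENSE_SCHEDULE)
    conv = conv or ConvergenceSpec()
    A = inst.A
    b = np.asarray(inst.b, dtype=float)
    c = np.asarray(inst.c, dtype=float)
    d = float(inst.d)
    x = np.asarray(inst.x, dtype=float)
    m, n = A.shape

    def split(state):
        return state[:n], state[n : n + m], float(state[-1])

    def loss(state):
        u = state[:n]
        return 0.5 * float(np.sum((x - u) ** 2))

    def apply_lorentz(state):
        u, w, r = split(state)
        wt, rt = project_lorentz(w, r)
        return np.concatenate([u, wt, [rt]])

    lorentz_op = ProjectionOperator("lorentz_split", apply_lorentz)

    if sparse or backend == "iterative_lsq":
        A_csr = sp.csr_matrix(A)

        def solve_system(rhs, rho):
            def mv(u):
                return u / rho + A_csr.T @ (A_csr @ u) + c * (c @ u)

            op = LinearOperator((n, n), matvec=mv)
            sol, info = cg(op, rhs, rtol=1e-12, atol=0.0, maxiter=4 * n + 100)
            return sol
    else:
        gram = linear_backend(
            "cached_spectral", np.asarray(A, dtype=float).T @ A + np.outer(c, c)
        )

        def solve_system(rhs, rho):
            return gram.solve(rhs, shift=1.0 / rho)

    def step(y, rho, anchor):
        _, wt, rt = split(y)
        rhs = x / rho + A.T @ (wt - b) + (rt - d) * c
        u = solve_system(rhs, rho)
        w = A @ u + b
        r = float(c @ u + d)
        return np.concatenate([u, w, [r]])

    u0 = x.copy()
    state0 = np.concatenate([u0, A @ u0 + b, [float(c @ u0 + d)]])
    problem = ProximalDistanceProblem(
        loss=loss, step=step, projections=[lorentz_op], x0=state0
    )
    result = run(problem, schedule, conv, accelerate=accelerate)
    u, w, r = split(result.solution)
    result.solution = u
    result.extras["objective"] = 0.5 * float(np.sum((x - u) ** 2))
    result.extras["cone_violation"] = max(0.0, float(np.linalg.norm(A @ u + b) - (c @ u + d)))
    return result


# ---------------------------------------------------------------------------
# Linear complementarity
# ---------------------------------------------------------------------------


def solve_lcp(
    inst: LCPInstance,
    schedule: PenaltySchedule | None = None,
    conv: ConvergenceSpec | None = None,
    accelerate: bool = True,
    backend: str | None = None,
    restarts: int = 20,
    seed: int | None = 0,
) -> SolveResult:
    """LCP by penalizing distance to the complementarity set, with multistart.

    Loss ``½‖y − Ax − b‖²`` over the pair state ``(x, y)``; the projection
    picks, per component, the nearest of ``(u_i, 0)``, ``(0, v_i)`` and
    ``(0, 0)``.  The x-update solves ``[(1+ρ)I + AᵗA]x = Aᵗ(ỹ − b) + (1+ρ)x̃``
    through a cached spectral factorization of AᵗA.

    The complementarity set is nonconvex and a single run can stall in a
    local minimum, so up to ``restarts`` runs are taken — the deterministic
    start ``(0, b)`` first, then seeded nonnegative random states — stopping
    early as soon as one attains (numerically) zero loss.  The best run is
    returned; failure to reach zero loss is reported, not raised.
    """
    schedule = schedule or LCP_SCHEDULE
    conv = conv or ConvergenceSpec()
    A = np.asarray(inst.A, dtype=float)
    b = np.asarray(inst.b, dtype=float)
    n = A.shape[0]
    gram = linear_backend("cached_spectral", A.T @ A)

    def loss(state):
        xs, ys = state[:n], state[n:]
        return 0.5 * float(np.sum((ys - A @ xs - b) ** 2))

    def apply_comp(state):
        xs, ys = project_complementarity(state[:n], state[n:])
        return np.concatenate([xs, ys])

    comp_op = ProjectionOperator("complementarity", apply_comp)

    def step(y, rho, anchor):
        xt, yt = y[:n], y[n:]
        x_next = gram.solve(A.T @ (yt - b) + (1.0 + rho) * xt, shift=1.0 + rho)
        y_next = (A @ x_next + b) / (1.0 + rho) + rho * yt / (1.0 + rho)
        return np.concatenate([x_next, y_next])

    rng = np.random.default_rng(seed)
    result = None
    n_runs = 0
    for attempt in range(max(1, restarts)):
        if attempt == 0:
            state0 = np.concatenate([np.zeros(n), b])
        else:
            state0 = np.abs(rng.standard_normal(2 * n))
        problem = ProximalDistanceProblem(
            loss=loss, step=step, projections=[comp_op], x0=state0
        )
        res = run(problem, schedule, conv, accelerate=accelerate)
        n_runs += 1
        if result is None or res.loss_value < result.loss_value:
            result = res
        if result.loss_value <= 1e-8:
            break

    xs, ys = result.solution[:n], result.solution[n:]
    result.extras["x"] = xs
    result.extras["y"] = ys
    result.extras["complementarity_residual"] = float(abs(xs @ ys))
    result.extras["link_residual"] = float(np.linalg.norm(ys - A @ xs - b))
    result.extras["restarts_used"] = n_runs
    return result
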