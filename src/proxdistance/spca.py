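"""Sparse principal components by MM over the Stiefel manifold.

The first q principal components maximize tr(UᵗSU) over the Stiefel manifold
of p×q matrices with orthonormal columns, where S = XᵗX/n is the sample
covariance.  Sparsity is imposed by constraining each column of U to at most
r nonzero entries (column mode), or the whole matrix to at most r nonzeros
(matrix mode, which lets the algorithm distribute nonzeros unevenly across
loadings).  The Stiefel constraint lives in the domain of the objective and
the sparsity constraint in the distance penalty, giving the MM update

    U_{k+1} = P_Stiefel[ S U_k + ρ P_sparsity(U_k) ],

a single thin SVD per iteration.  Because S is PSD, each update decreases
−½tr(UᵗSU) + (ρ/2)·dist(U, S_r)² over the manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from .engine import ConvergenceSpec, PenaltySchedule, ProximalDistanceProblem, run
from .projections import ProjectionOperator, project_sparsity, project_stiefel

__all__ = ["SPCAProblem", "SPCAResult", "spca_step", "solve_spca", "pve", "SPCA_SCHEDULE"]

SPCA_SCHEDULE = PenaltySchedule(1.0, 2.0, 100)


@dataclass
class SPCAProblem:
    """Sparse PCA instance: data matrix X (or covariance S), q components,
    sparsity budget r, and the budget mode.

    ``X`` is centered column-wise on construction if needed.  In matrix mode
    the budget must admit at least one nonzero per column (r ≥ q).
    """

    X: np.ndarray | None = None
    S: np.ndarray | None = None
    q: int = 1
    r: int = 1
    mode: str = "column"

    def __post_init__(self):
        if (self.X is None) == (self.S is None):
            raise ValueError("supply exactly one of X or S")
        if self.X is not None:
            X = np.asarray(self.X, dtype=float)
            means = X.mean(axis=0)
            if np.max(np.abs(means)) > 1e-8:
                X = X - means
            self.X = X
            self.S = X.T @ X / X.shape[0]
        else:
            S = np.asarray(self.S, dtype=float)
            self.S = 0.5 * (S + S.T)
        p = self.S.shape[0]
        if not 1 <= self.q <= p:
            raise ValueError("require 1 <= q <= p")
        if self.mode == "matrix" and self.r < self.q:
            raise ValueError("matrix mode needs r >= q")
        if self.mode == "column" and not 1 <= self.r <= p:
            raise ValueError("column mode needs 1 <= r <= p")
        if self.mode not in ("column", "matrix"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SPCAResult:
    U: np.ndarray
    pve: float
    objective: float
    iterations: int
    converged: bool
    extras: dict = field(default_factory=dict)


def spca_step(S: np.ndarray, Uk: np.ndarray, rho: float, r: int, mode: str = "column") -> np.ndarray:
    """One MM update: Stiefel projection of ``S U_k + ρ P_sparsity(U_k)``."""
    return project_stiefel(S @ Uk + rho * project_sparsity(Uk, r, mode))


def _sign_fix(U: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic)."""
    U = U.copy()
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


def _polish(U: np.ndarray, r: int, mode: str, rounds: int = 100) -> np.ndarray:
    """Alternate sparsity/Stiefel projections until the sparsification is a
    no-op, ending with the sparsity projection so the budget holds exactly
    while orthonormality is preserved to roundoff."""
    for _ in range(rounds):
        Us = project_sparsity(U, r, mode)
        if np.linalg.norm(U - Us) <= 1e-10:
            return Us
        U = project_stiefel(Us)
    return project_sparsity(U, r, mode)


def solve_spca(
    prob: SPCAProblem,
    schedule: PenaltySchedule | None = None,
    conv: ConvergenceSpec | None = None,
    accelerate: bool = True,
    seed: int | None = None,
    restarts: int = 10,
) -> SPCAResult:
    """Fit sparse loadings by proximal distance MM with rotation multistart.

    The deterministic first start is the top-q eigenvector basis of S (the
    unconstrained PCA solution).  When the leading eigenvalues are close the
    eigenbasis is an arbitrary rotation of the sparse directions and the
    sparsity projection can lock onto a mixed support, so further starts
    rotate the initial frame by seeded Haar-random q×q orthogonal matrices;
    the run with the best final objective wins.  In matrix mode with an
    evenly divisible budget, the column-mode solution (feasible under the
    matrix budget) seeds one extra start, so the freer budget never loses to
    the restricted one.  After convergence the loadings are polished onto the
    exact intersection of budget and orthonormality, sign-normalized, and
    scored by PVE.
    """
    schedule = schedule or SPCA_SCHEDULE
    conv = conv or ConvergenceSpec(max_iter=2000)
    S, q, r, mode = prob.S, prob.q, prob.r, prob.mode
    p = S.shape[0]

    d, V = eigh(S)
    U0 = V[:, ::-1][:, :q]  # top-q eigenvectors

    sparsity_op = ProjectionOperator(
        f"sparsity_{mode}", lambda U: project_sparsity(U, r, mode)
    )

    def loss(U):
        return -0.5 * float(np.trace(U.T @ S @ U))

    def step(y, rho, anchor):
        return project_stiefel(S @ anchor + rho * y)

    starts = [U0]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, restarts - 1)):
        Q, _ = np.linalg.qr(rng.standard_normal((q, q)))
        starts.append(U0 @ Q)
    extra_candidates = []
    if mode == "matrix" and q > 1 and r % q == 0:
        col = solve_spca(
            SPCAProblem(S=S, q=q, r=r // q, mode="column"),
            schedule, conv, accelerate, seed, restarts,
        )
        starts.append(col.U)
        # the column solution is itself matrix-feasible: keep it in the pool
        extra_candidates.append(col.U)

    best_U = None
    best_obj = -np.inf
    best_meta = (0, True)
    for U_cand in extra_candidates:
        obj = float(np.trace(U_cand.T @ S @ U_cand))
        if obj > best_obj:
            best_U, best_obj = U_cand, obj
            best_meta = (col.iterations, col.converged)
    for x0 in starts:
        problem = ProximalDistanceProblem(
            loss=loss, step=step, projections=[sparsity_op], x0=x0
        )
        res = run(problem, schedule, conv, accelerate=accelerate)
        U_cand = _sign_fix(_polish(res.solution, r, mode))
        obj = float(np.trace(U_cand.T @ S @ U_cand))
        if obj > best_obj:
            best_U, best_obj = U_cand, obj
            best_meta = (res.iterations, res.converged)

    U, objective = best_U, best_obj
    iterations, conv_flag = best_meta
    if prob.X is not None:
        explained = pve(prob.X, U)
    else:
        G = U.T @ U
        explained = float(np.trace(np.linalg.solve(G, U.T @ S @ U)) / np.trace(S))
    nnz = [int(np.count_nonzero(U[:, j])) for j in range(U.shape[1])]
    return SPCAResult(
        U=U,
        pve=explained,
        objective=objective,
        iterations=iterations,
        converged=conv_flag,
        extras={"nnz_per_column": nnz},
    )


def pve(X: np.ndarray, U: np.ndarray) -> float:
    """Proportion of variance explained: tr(X_qᵗX_q)/tr(XᵗX) with
    ``X_q = XU(UᵗU)⁻¹Uᵗ``; reduces to tr(UᵗXᵗXU)/tr(XᵗX) for orthonormal U."""
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    total = float(np.sum(X * X))
    if total == 0.0:
        raise ValueError("tr(XᵗX) is zero; PVE undefined")
    B = X @ U
    G = U.T @ U
    # tr(X_qᵗX_q) = tr(G⁻¹·BᵗB); requires U of full column rank
    return float(np.trace(np.linalg.solve(G, B.T @ B)) / total)
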