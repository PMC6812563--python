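"""Generic MM driver for proximal distance algorithms.

The proximal distance principle attacks ``min f(x) subject to x ∈ ∩ᵢ Cᵢ`` by
minimizing the penalized loss

    h_ρ(x) = f(x) + (ρ/2) Σᵢ αᵢ dist(x, Cᵢ)²

and driving ρ upward along a schedule.  Each squared distance is majorized by
the spherical quadratic ``‖x − P_Cᵢ(x_k)‖²``, so one MM iteration anchors the
surrogate at the convex combination ``y_k = Σᵢ αᵢ P_Cᵢ(x_k)`` and minimizes
``f(x) + (ρ/2)‖x − y_k‖²`` — a proximal map for most losses, a specialized
linear-algebra solve for the solvers in this package.  The next iterate can
never increase h_ρ at fixed ρ (the MM descent property).

Nesterov extrapolation is applied to the *anchor*: the algorithm map is
evaluated at the shifted point ``z_k = x_k + (k−1)/(k+d−1)·(x_k − x_{k−1})``.
Because the extrapolation assumes a fixed objective, the momentum counter and
memory reset whenever ρ increases; acceleration therefore operates within each
fixed-ρ epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PenaltySchedule",
    "ConvergenceSpec",
    "ProximalDistanceProblem",
    "SolveResult",
    "TraceRecord",
    "run",
    "nesterov_point",
    "converged",
    "prop1_bound",
    "set_projection_problem",
]

#: default extrapolation offset in the Nesterov sequence (k−1)/(k+d−1)
NESTEROV_D = 3.0

#: default cap on the penalty constant; ρ is never driven literally to
#: infinity because huge ρ only amplifies roundoff without improving the
#: solution beyond the O(1/ρ) penalty-method error
DEFAULT_RHO_CAP = float(2**22)


@dataclass(frozen=True)
class PenaltySchedule:
    """Geometric penalty schedule ``ρ_k = min(cap, ρ₀·g^⌊k/period⌋)``.

    Parameters
    ----------
    rho_init : float
        Starting penalty ρ₀ > 0.
    growth_factor : float
        Multiplier g ≥ 1 applied every ``update_period`` iterations.
    update_period : int
        Number of iterations between increases.
    rho_cap : float
        Upper bound on ρ (defaults to 2²²).
    """

    rho_init: float = 1.0
    growth_factor: float = 2.0
    update_period: int = 100
    rho_cap: float = DEFAULT_RHO_CAP

    def __post_init__(self) -> None:
        if self.rho_init <= 0:
            raise ValueError("rho_init must be positive")
        if self.growth_factor < 1:
            raise ValueError("growth_factor must be >= 1")
        if self.update_period < 1:
            raise ValueError("update_period must be a positive integer")
        if self.rho_cap <= 0:
            raise ValueError("rho_cap must be positive")

    def rho_at(self, k: int) -> float:
        """Penalty constant at iteration k ≥ 0."""
        if k < 0:
            raise ValueError("iteration index must be nonnegative")
        epochs = k // self.update_period
        # work in logs to survive huge exponents before the cap kicks in
        log_rho = np.log(self.rho_init) + epochs * np.log(self.growth_factor)
        if log_rho >= np.log(self.rho_cap):
            return float(self.rho_cap)
        return float(min(self.rho_cap, self.rho_init * self.growth_factor**epochs))


@dataclass(frozen=True)
class ConvergenceSpec:
    """Stopping criteria: relative loss stagnation and constraint distance.

    Iteration k is declared converged when both

        |f(x_k) − f(x_{k−1})| ≤ eps_loss·(|f(x_{k−1})| + 1)
        dist(x_k, C) ≤ eps_dist

    hold.  The defaults eps_loss = 1e−6 and eps_dist = 1e−4 are the values
    used throughout the worked examples.
    """

    eps_loss: float = 1e-6
    eps_dist: float = 1e-4
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.eps_loss <= 0 or self.eps_dist <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")


@dataclass
class ProximalDistanceProblem:
    """Bundle of a loss, its surrogate-minimizing step, and projections.

    Attributes
    ----------
    loss : callable
        ``f(x) -> float``, the unpenalized loss.
    step : callable
        ``step(y, rho, anchor) -> x`` minimizing the surrogate
        ``g_ρ(x | anchor) = f(x) + (ρ/2)‖x − y‖²`` (possibly over a domain
        folded into the loss).  ``anchor`` is the point the surrogate is
        anchored at (x_k, or the shifted z_k under acceleration); most steps
        ignore it.
    projections : sequence of (ProjectionOperator, weight)
        Constraint sets Cᵢ with convex weights αᵢ ≥ 0, Σαᵢ = 1.  Passing bare
        operators assigns the neutral weights αᵢ = 1/m.
    x0 : ndarray, optional
        Starting point; if absent, ``init(rng)`` is called.
    init : callable, optional
        Seeded initializer ``init(rng) -> x0``.
    """

    loss: Callable[[np.ndarray], float]
    step: Callable[[np.ndarray, float, np.ndarray], np.ndarray]
    projections: Sequence
    x0: np.ndarray | None = None
    init: Callable[[np.random.Generator], np.ndarray] | None = None

    def normalized_projections(self):
        ops = []
        for item in self.projections:
            if isinstance(item, tuple):
                ops.append(item)
            else:
                ops.append((item, None))
        m = len(ops)
        if m == 0:
            raise ValueError("problem has no constraint projections")
        weights = [w for _, w in ops]
        if all(w is None for w in weights):
            ops = [(op, 1.0 / m) for op, _ in ops]
        elif any(w is None for w in weights):
            raise ValueError("either give all projection weights or none")
        total = sum(w for _, w in ops)
        if any(w < 0 for _, w in ops) or abs(total - 1.0) > 1e-12:
            raise ValueError("projection weights must be nonnegative and sum to 1")
        return ops


@dataclass
class TraceRecord:
    k: int
    rho: float
    loss: float
    dist: float


@dataclass
class SolveResult:
    """Outcome of a proximal distance run."""

    solution: np.ndarray
    loss_value: float
    penalized_value: float
    constraint_distance: float
    iterations: int
    converged: bool
    trace: list[TraceRecord] | None = None
    message: str = ""
    extras: dict = field(default_factory=dict)

    def trace_tsv(self) -> str:
        """Trace as tab-separated records (k, rho, loss, dist)."""
        lines = ["k\trho\tloss\tdist"]
        for rec in self.trace or []:
            lines.append(f"{rec.k}\t{rec.rho:.17g}\t{rec.loss:.17g}\t{rec.dist:.17g}")
        return "\n".join(lines) + "\n"


def nesterov_point(x_k: np.ndarray, x_prev: np.ndarray, k: int, d: float = NESTEROV_D) -> np.ndarray:
    """Extrapolated anchor ``x_k + (k−1)/(k+d−1)·(x_k − x_prev)``.

    Preserves any affine constraint satisfied by both arguments, since the
    result is an affine combination with coefficients summing to one.
    """
    if k < 1:
        raise ValueError("Nesterov counter k must be >= 1")
    if d <= 0:
        raise ValueError("offset d must be positive")
    coeff = (k - 1.0) / (k + d - 1.0)
    return x_k + coeff * (x_k - x_prev)


def converged(f_k: float, f_prev: float, dist_k: float, conv: ConvergenceSpec) -> bool:
    """Both stopping criteria: loss stagnation and constraint proximity."""
    return (
        abs(f_k - f_prev) <= conv.eps_loss * (abs(f_prev) + 1.0)
        and dist_k <= conv.eps_dist
    )


def prop1_bound(rho: float, k: int, x0: np.ndarray, z: np.ndarray) -> float:
    """Sublinear bound ``ρ‖z − x0‖²/(2(k+1))`` on ``h_ρ(x_{k+1}) − h_ρ(z*)``.

    Valid for convex losses and convex constraint sets at fixed ρ; used as a
    test oracle for the O(ρ/k) convergence rate.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    diff = np.ravel(np.asarray(z, dtype=float) - np.asarray(x0, dtype=float))
    return float(rho * (diff @ diff) / (2.0 * (k + 1)))


def _weighted_anchor(ops, z):
    y = None
    for op, w in ops:
        pz = np.asarray(op.apply(z), dtype=float)
        y = w * pz if y is None else y + w * pz
    return y


def _constraint_distance(ops, x):
    return max(op.distance(x) for op, _ in ops)


def run(
    problem: ProximalDistanceProblem,
    schedule: PenaltySchedule | None = None,
    conv: ConvergenceSpec | None = None,
    accelerate: bool = False,
    seed: int | None = None,
    d: float = NESTEROV_D,
    keep_trace: bool = True,
    loss_floor: float = -1e12,
) -> SolveResult:
    """Run the proximal distance iteration to convergence or ``max_iter``.

    One iteration forms the anchor (x_k, or the Nesterov-shifted z_k), takes
    the convex combination of its projections, and calls ``problem.step``.
    Convergence is only tested at iterations where ρ did not just increase, so
    the loss-stagnation criterion always compares values under the same
    penalty.  A loss below ``loss_floor`` stops the run with an
    unbounded-suspect message rather than an exception.
    """
    schedule = schedule or PenaltySchedule()
    conv = conv or ConvergenceSpec()
    ops = problem.normalized_projections()

    if problem.x0 is not None:
        x = np.array(problem.x0, dtype=float)
    elif problem.init is not None:
        x = np.asarray(problem.init(np.random.default_rng(seed)), dtype=float)
    else:
        raise ValueError("problem supplies neither x0 nor init")

    f = float(problem.loss(x))
    if not np.isfinite(f):
        raise FloatingPointError("loss is non-finite at the starting point")

    x_prev = x
    nesterov_k = 0
    rho_prev = schedule.rho_at(0)
    trace: list[TraceRecord] = [] if keep_trace else None
    streak = 0
    flag = False
    message = "max_iter reached"
    n_iter = 0
    rho = rho_prev

    for k in range(conv.max_iter):
        rho = schedule.rho_at(k)
        rho_changed = rho != rho_prev
        if accelerate:
            if rho_changed:
                # new fixed-ρ epoch: restart the momentum sequence
                nesterov_k = 1
                x_prev = x
            else:
                nesterov_k += 1
            z = nesterov_point(x, x_prev, nesterov_k, d)
        else:
            z = x

        y = _weighted_anchor(ops, z)
        x_next = np.asarray(problem.step(y, rho, z), dtype=float)
        f_next = float(problem.loss(x_next))
        if not np.isfinite(f_next):
            raise FloatingPointError(f"non-finite loss at iteration {k}")
        dist = _constraint_distance(ops, x_next)
        n_iter = k + 1
        if keep_trace:
            trace.append(TraceRecord(k, rho, f_next, dist))

        if f_next < loss_floor:
            x, f = x_next, f_next
            message = "unbounded-suspect: loss fell below the divergence floor"
            break

        # require the criteria at two consecutive eligible iterations: right
        # after a momentum reset a single tiny step can mimic stagnation
        if (not rho_changed) and converged(f_next, f, dist, conv):
            streak += 1
        else:
            streak = 0
        if streak >= 2:
            x, f = x_next, f_next
            flag = True
            message = "converged"
            break

        x_prev = x
        x, f = x_next, f_next
        rho_prev = rho

    dist = _constraint_distance(ops, x)
    penalty = 0.5 * rho * sum(w * op.distance(x) ** 2 for op, w in ops)
    return SolveResult(
        solution=x,
        loss_value=f,
        penalized_value=f + penalty,
        constraint_distance=dist,
        iterations=n_iter,
        converged=flag,
        trace=trace,
        message=message,
    )


def set_projection_problem(z: np.ndarray, projections: Sequence) -> ProximalDistanceProblem:
    """Projection of an external point ``z`` onto an intersection of sets.

    With loss ``f(x) = ½‖z − x‖²`` the surrogate minimizer is the explicit
    convex combination ``x_{k+1} = (z + ρ y_k)/(1 + ρ)``.
    """
    z = np.asarray(z, dtype=float)

    def loss(x):
        return 0.5 * float(np.sum((z - x) ** 2))

    def step(y, rho, anchor):
        return (z + rho * y) / (1.0 + rho)

    return ProximalDistanceProblem(loss=loss, step=step, projections=projections, x0=z.copy())
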