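"""Nearest-point maps onto the constraint sets used by the solvers.

Every operator here returns a *single* deterministic representative of the
(possibly multi-valued) nearest-point set.  All magnitude/argmax ties break
toward the lowest index so that solver traces are reproducible.  For a convex
set ``C`` the map is the unique Euclidean projection and is nonexpansive; the
gradient identity ``∇ ½ dist(x, C)² = x − P_C(x)`` holds wherever the
projection is single valued, which makes the squared-distance penalty smooth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import eigh, svd

__all__ = [
    "ProjectionOperator",
    "AffineProjector",
    "project_affine",
    "project_nonnegative",
    "project_simplex",
    "project_psd",
    "project_kinship_structure",
    "project_lorentz",
    "project_sphere_nonneg",
    "project_complementarity",
    "project_sparsity",
    "project_stiefel",
    "project_graph_manifold",
    "prox_inequality_bisection",
    "nonnegative_operator",
    "simplex_operator",
    "psd_operator",
    "kinship_structure_operator",
    "sphere_nonneg_operator",
]


@dataclass(frozen=True)
class ProjectionOperator:
    """A named nearest-point map ``apply`` with its induced distance.

    ``distance(x)`` defaults to ``‖x − apply(x)‖`` (Frobenius norm for
    matrix-shaped points), which is the Euclidean distance to the set whenever
    ``apply`` is an exact projection.
    """

    name: str
    apply: Callable[[np.ndarray], np.ndarray]
    _distance: Callable[[np.ndarray], float] | None = field(default=None, repr=False)

    def distance(self, x: np.ndarray) -> float:
        if self._distance is not None:
            return self._distance(x)
        return float(np.linalg.norm(np.ravel(x - self.apply(x))))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.apply(x)


# ---------------------------------------------------------------------------
# Affine sets {x : Ax = b}
# ---------------------------------------------------------------------------


class AffineProjector:
    """Projection onto ``{x : Ax = b}`` with a cached pseudo-inverse.

    The pseudo-inverse ``A⁻ = Aᵗ(AAᵗ)⁻¹`` is built once from an economy SVD
    with singular values below ``max(m, n)·eps·σ_max`` discarded, then reused
    for every projection.  With ``allow_rank_deficient=False`` a rank-deficient
    ``A`` is rejected instead of silently truncated.
    """

    def __init__(self, A: np.ndarray, b: np.ndarray, allow_rank_deficient: bool = False):
        A = np.asarray(A, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        b = np.asarray(b, dtype=float).ravel()
        m, n = A.shape
        if b.shape[0] != m:
            raise ValueError(f"b has length {b.shape[0]}, expected {m}")
        U, s, Vt = svd(A, full_matrices=False)
        cutoff = max(m, n) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        rank = int(np.sum(s > cutoff))
        if rank < min(m, n) and not allow_rank_deficient:
            raise np.linalg.LinAlgError(
                f"A is rank deficient (rank {rank} < {min(m, n)}); "
                "pass allow_rank_deficient=True to project via the truncated SVD"
            )
        self.A = A
        self.b = b
        self._U = U[:, :rank]
        self._s = s[:rank]
        self._Vt = Vt[:rank]

    def pinv_apply(self, z: np.ndarray) -> np.ndarray:
        """Apply the cached pseudo-inverse: ``A⁻ z``."""
        return self._Vt.T @ ((self._U.T @ z) / self._s)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return x - self.pinv_apply(self.A @ x - self.b)

    def distance(self, x: np.ndarray) -> float:
        return float(np.linalg.norm(x - self.apply(x)))

    def as_operator(self) -> ProjectionOperator:
        return ProjectionOperator("affine", self.apply, self.distance)


def project_affine(
    A: np.ndarray,
    b: np.ndarray,
    x: np.ndarray,
    pinv_cache: AffineProjector | None = None,
) -> np.ndarray:
    """Project ``x`` onto ``{x : Ax = b}``; ``x − A⁻(Ax − b)``."""
    proj = pinv_cache if pinv_cache is not None else AffineProjector(A, b)
    return proj.apply(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Orthant and simplex
# ---------------------------------------------------------------------------


def project_nonnegative(x: np.ndarray) -> np.ndarray:
    """Componentwise ``max(x_i, 0)`` — projection onto the nonnegative orthant."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def project_simplex(x: np.ndarray) -> np.ndarray:
    """Project onto the probability simplex ``{x ≥ 0, Σx = 1}``.

    Sort-based thresholding: the projection is ``(x − τ)₊`` where τ is found
    from the sorted entries in O(n log n).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot project an empty vector onto the simplex")
    u = np.sort(x)[::-1]
    css = np.cumsum(u) - 1.0
    ks = np.arange(1, x.size + 1)
    cond = u - css / ks > 0
    k = ks[cond][-1]
    tau = css[k - 1] / k
    return np.maximum(x - tau, 0.0)


# ---------------------------------------------------------------------------
# Matrix cones
# ---------------------------------------------------------------------------


def project_psd(X: np.ndarray) -> np.ndarray:
    """Frobenius-nearest positive semidefinite matrix.

    The input is symmetrized as ``(X + Xᵗ)/2`` first to absorb accumulated
    numerical asymmetry, then negative eigenvalues are truncated.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("project_psd requires finite entries")
    S = 0.5 * (X + X.T)
    d, U = eigh(S)
    d = np.maximum(d, 0.0)
    return (U * d) @ U.T


def project_kinship_structure(X: np.ndarray) -> np.ndarray:
    """Structural kinship constraints: diagonal ½, off-diagonals clamped at 0.

    A valid (non-inbred) kinship matrix has every self-kinship equal to ½ and
    nonnegative pairwise coefficients; this resets the diagonal and clamps.
    """
    X = np.asarray(X, dtype=float)
    out = np.maximum(X, 0.0)
    np.fill_diagonal(out, 0.5)
    return out


def project_lorentz(w: np.ndarray, r: float) -> tuple[np.ndarray, float]:
    """Project ``(w, r)`` onto the second-order (Lorentz) cone ``{‖w‖ ≤ r}``."""
    w = np.asarray(w, dtype=float)
    nw = float(np.linalg.norm(w))
    if nw <= r:
        return w.copy(), float(r)
    if nw <= -r:  # in the polar cone: nearest point is the apex
        return np.zeros_like(w), 0.0
    scale = (r + nw) / 2.0
    return scale * (w / nw), scale


def project_sphere_nonneg(y: np.ndarray) -> np.ndarray:
    """Project onto the unit sphere intersected with the nonnegative orthant.

    If any component is positive, zero out the negatives and normalize.
    Otherwise return the unit vector along the largest (least negative)
    component; ties and the origin break toward the lowest index.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty vector")
    if np.max(y) > 0:
        z = np.maximum(y, 0.0)
        return z / np.linalg.norm(z)
    e = np.zeros_like(y)
    e[int(np.argmax(y))] = 1.0  # argmax of all-zero y is index 0
    return e


def project_complementarity(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Componentwise nearest pair with ``x ≥ 0, y ≥ 0, xᵗy = 0``.

    Per component: ``(u_i, 0)`` when ``u_i ≥ max(v_i, 0)``, ``(0, v_i)`` when
    ``v_i ≥ max(u_i, 0)`` and otherwise ``(0, 0)``; exact ties take the first
    rule.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("u and v must have equal length")
    x = np.zeros_like(u)
    y = np.zeros_like(v)
    take_u = u >= np.maximum(v, 0.0)
    take_v = (~take_u) & (v >= np.maximum(u, 0.0))
    x[take_u] = u[take_u]
    y[take_v] = v[take_v]
    return x, y


# ---------------------------------------------------------------------------
# Sparsity and the Stiefel manifold
# ---------------------------------------------------------------------------


def _keep_largest(v: np.ndarray, r: int) -> np.ndarray:
    # stable sort on -|v| keeps the lowest index among tied magnitudes
    order = np.argsort(-np.abs(v), kind="stable")
    out = np.zeros_like(v)
    keep = order[:r]
    out[keep] = v[keep]
    return out


def project_sparsity(U: np.ndarray, r: int, mode: str = "column") -> np.ndarray:
    """Keep the ``r`` largest-magnitude entries per column (or matrix-wide).

    Magnitude ties break toward the lowest (flattened) index.
    """
    if r <= 0:
        raise ValueError("sparsity budget r must be positive")
    U = np.asarray(U, dtype=float)
    if mode == "column":
        if U.ndim == 1:
            return _keep_largest(U, r)
        return np.column_stack([_keep_largest(U[:, j], r) for j in range(U.shape[1])])
    if mode == "matrix":
        flat = _keep_largest(U.ravel(), r)
        return flat.reshape(U.shape)
    raise ValueError(f"unknown sparsity mode {mode!r}")


def project_stiefel(U: np.ndarray) -> np.ndarray:
    """Nearest matrix with orthonormal columns: ``VWᵗ`` from the thin SVD."""
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    p, q = U.shape
    if p < q:
        raise ValueError("Stiefel projection requires p >= q")
    V, s, Wt = svd(U, full_matrices=False)
    tol = max(p, q) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    if s.size and s[-1] <= tol:
        warnings.warn(
            "rank-deficient input to project_stiefel; null directions completed "
            "deterministically from the SVD basis",
            RuntimeWarning,
            stacklevel=2,
        )
    return V @ Wt


# ---------------------------------------------------------------------------
# Parameter splitting and convex-inequality prox
# ---------------------------------------------------------------------------


def project_graph_manifold(
    u: np.ndarray, v: np.ndarray, A: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest ``(x, y)`` to ``(u, v)`` with ``y = Ax`` (graph of ``A``).

    Solves ``x = (I + AᵗA)⁻¹(Aᵗv + u)``; when ``A`` is n×p with n < p the
    Woodbury identity routes the solve through the smaller n×n system.
    """
    A = np.asarray(A, dtype=float)
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    n, p = A.shape
    w = u + A.T @ v
    if n < p:
        x = w - A.T @ np.linalg.solve(np.eye(n) + A @ A.T, A @ w)
    else:
        x = np.linalg.solve(np.eye(p) + A.T @ A, w)
    return x, A @ x


def prox_inequality_bisection(
    prox_a: Callable[[float, np.ndarray], np.ndarray],
    a: Callable[[np.ndarray], float],
    t: float,
    y: np.ndarray,
    tol: float = 1e-10,
    max_expand: int = 200,
    max_bisect: int = 200,
) -> np.ndarray:
    """Project ``y`` onto ``{x : a(x) ≤ t}`` for convex ``a`` via its prox.

    The multiplier λ in the stationarity condition ``x = prox_{λa}(y)``,
    ``a(x) = t`` is bracketed by doubling and then located by bisection,
    exploiting that ``a(prox_{λa}(y))`` is decreasing in λ.
    """
    y = np.asarray(y, dtype=float)
    if a(y) <= t:
        return y.copy()
    lo, hi = 0.0, 1.0
    val = a(prox_a(hi, y))
    n_expand = 0
    while val > t:
        lo, hi = hi, 2.0 * hi
        val = a(prox_a(hi, y))
        n_expand += 1
        if n_expand > max_expand:
            raise RuntimeError(
                "prox_inequality_bisection: failed to bracket the multiplier "
                f"within {max_expand} doublings (a still {val:.3e} > t={t:.3e})"
            )
    x = prox_a(hi, y)
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        x = prox_a(mid, y)
        if a(x) > t:
            lo = mid
        else:
            hi = mid
        if abs(a(x) - t) <= tol:
            return x
    return prox_a(hi, y)


# ---------------------------------------------------------------------------
# Ready-made operators
# ---------------------------------------------------------------------------

nonnegative_operator = ProjectionOperator("nonnegative", project_nonnegative)
simplex_operator = ProjectionOperator("simplex", project_simplex)
psd_operator = ProjectionOperator("psd", project_psd)
kinship_structure_operator = ProjectionOperator("kinship_structure", project_kinship_structure)
sphere_nonneg_operator = ProjectionOperator("sphere_nonneg", project_sphere_nonneg)
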