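"""Seeded generators for solvable random test instances and fixed fixtures.

The numerical experiments the solvers are designed around use randomly
generated data: standard-normal fills at stated sparsity levels, symmetrized
square matrices for kinship candidates, and the printed Horn matrix family
for copositivity.  The original constructions do not specify how linear
programs and complementarity problems were made solvable, so the generators
here plant feasible/bounded structure explicitly (documented per function);
every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .affine_solvers import LCPInstance, LPInstance, SimplexLSInstance, SOCInstance
from .matrix_solvers import KinshipCandidate

__all__ = [
    "SyntheticInstance",
    "horn_matrix",
    "gen_lp_instance",
    "gen_ls_instance",
    "gen_kinship_candidate",
    "gen_soc_instance",
    "gen_lcp_instance",
    "gen_spiked_spca",
]


@dataclass
class SyntheticInstance:
    """Generated payload with its provenance (generator, parameters, seed)."""

    payload: object
    generator: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def manifest(self) -> dict:
        return {
            "generator": self.generator,
            "parameters": self.parameters,
            "seed": self.seed,
        }


def horn_matrix(n: int) -> np.ndarray:
    """Circulant ±1 matrix of the Horn pattern: −1 on cyclically adjacent
    pairs, +1 elsewhere (including the diagonal).

    The 5×5 member is the classical Horn matrix with variational index 0 —
    copositive yet not expressible as PSD plus nonnegative.  Odd dimensions
    share the copositivity property; even dimensions follow the same entry
    pattern but carry no such guarantee.
    """
    if n < 3:
        raise ValueError("Horn pattern needs n >= 3")
    M = np.ones((n, n))
    idx = np.arange(n)
    M[idx, (idx + 1) % n] = -1.0
    M[(idx + 1) % n, idx] = -1.0
    return M


def _sparse_normal(rng: np.random.Generator, m: int, n: int, density: float):
    nnz = max(1, int(round(density * m * n)))
    flat = rng.choice(m * n, size=nnz, replace=False)
    rows, cols = np.divmod(flat, n)
    vals = rng.standard_normal(nnz)
    return sp.csr_matrix((vals, (rows, cols)), shape=(m, n))


def gen_lp_instance(
    m: int, n: int, sparse: bool = False, density: float = 0.01, seed: int | None = None
) -> SyntheticInstance:
    """Random feasible, bounded linear program in standard form.

    A is standard normal (dense) or density-``density`` sparse normal;
    b = A·x₀ for a planted nonnegative x₀ = |N(0,1)| (feasibility), and
    v = Aᵗu + s with u ~ N(0, I) and s = |N(0,1)| entrywise, so v − Aᵗu ≥ 0
    certifies dual feasibility and a bounded optimum.
    """
    if not m < n:
        raise ValueError("standard-form generator expects m < n")
    rng = np.random.default_rng(seed)
    if sparse:
        A = _sparse_normal(rng, m, n, density)
    else:
        A = rng.standard_normal((m, n))
    x0 = np.abs(rng.standard_normal(n))
    b = A @ x0
    u = rng.standard_normal(m)
    s = np.abs(rng.standard_normal(n))
    v = A.T @ u + s
    inst = LPInstance(A=A, b=b, v=np.asarray(v).ravel())
    return SyntheticInstance(
        inst, "lp", {"m": m, "n": n, "sparse": sparse, "density": density}, seed
    )


def gen_ls_instance(
    n: int, p: int, sparse: bool = False, seed: int | None = None
) -> SyntheticInstance:
    """Simplex-constrained least squares data: A (n×p) and y standard normal;
    sparse A uses sparsity level 10/p."""
    rng = np.random.default_rng(seed)
    if sparse:
        A = _sparse_normal(rng, n, p, min(1.0, 10.0 / p))
    else:
        A = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    inst = SimplexLSInstance(A=A, y=y)
    return SyntheticInstance(inst, "simplexls", {"n": n, "p": p, "sparse": sparse}, seed)


def gen_kinship_candidate(n: int, seed: int | None = None) -> SyntheticInstance:
    """Standard-normal square matrix symmetrized by averaging opposing
    off-diagonal entries (off-diagonals therefore N(0, ½))."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, n))
    Y = 0.5 * (Z + Z.T)
    return SyntheticInstance(KinshipCandidate(Y), "kinship", {"n": n}, seed)


def gen_soc_instance(
    m: int, n: int, sparse: bool = False, density: float = 0.01, seed: int | None = None
) -> SyntheticInstance:
    """Second-order-cone projection instance with a nonempty constraint set.

    A, b, c and the external point x are standard normal; the offset is
    d = ‖b‖ + |N(0,1)|, which makes u = 0 strictly feasible by construction.
    """
    rng = np.random.default_rng(seed)
    if sparse:
        A = _sparse_normal(rng, m, n, density)
    else:
        A = rng.standard_normal((m, n))
    b = rng.standard_normal(m)
    c = rng.standard_normal(n)
    d = float(np.linalg.norm(b) + np.abs(rng.standard_normal()))
    x = rng.standard_normal(n)
    inst = SOCInstance(A=A, b=b, c=c, d=d, x=x)
    return SyntheticInstance(
        inst, "socproj", {"m": m, "n": n, "sparse": sparse, "density": density}, seed
    )


def gen_lcp_instance(
    n: int, seed: int | None = None, solvable: bool = True
) -> SyntheticInstance:
    """Linear complementarity instance; when ``solvable`` a complementary pair
    (x*, y*) with random support is planted and b = y* − A·x*, so the zero-loss
    solution exists by construction."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    if solvable:
        support = rng.random(n) < 0.5
        x_star = np.where(support, np.abs(rng.standard_normal(n)), 0.0)
        y_star = np.where(~support, np.abs(rng.standard_normal(n)), 0.0)
        b = y_star - A @ x_star
    else:
        b = rng.standard_normal(n)
    inst = LCPInstance(A=A, b=b)
    return SyntheticInstance(inst, "lcp", {"n": n, "solvable": solvable}, seed)


def gen_spiked_spca(
    n: int,
    p: int,
    q: int,
    r: int,
    signal: float = 5.0,
    noise: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spiked covariance model with disjoint r-sparse orthonormal loadings.

    Column j of the true loading matrix is supported on the index block
    ``[j·r, (j+1)·r)`` with random normal values normalized to unit norm
    (disjoint supports make the columns exactly orthonormal).  Data are
    ``scores·Uᵗ + noise`` with scores N(0, signal²) and i.i.d. N(0, noise²)
    noise; X is returned column-centered alongside the true loadings.
    """
    if q * r > p:
        raise ValueError("disjoint supports require q*r <= p")
    rng = np.random.default_rng(seed)
    U = np.zeros((p, q))
    for j in range(q):
        block = slice(j * r, (j + 1) * r)
        vals = rng.standard_normal(r)
        U[block, j] = vals / np.linalg.norm(vals)
    scores = signal * rng.standard_normal((n, q))
    X = scores @ U.T + noise * rng.standard_normal((n, p))
    X = X - X.mean(axis=0)
    return X, U
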