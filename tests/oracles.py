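"""Brute-force reference solvers used only as independent test oracles."""

import itertools

import numpy as np
from scipy.optimize import minimize


def lp_vertex_enumeration(A, b, v):
    """Exact optimum of ``min vᵗx, Ax = b, x ≥ 0`` by enumerating basic
    feasible points."""
    A = np.asarray(A, dtype=float)
    m, n = A.shape
    best, bx = np.inf, None
    for cols in itertools.combinations(range(n), m):
        B = A[:, cols]
        try:
            xb = np.linalg.solve(B, b)
        except np.linalg.LinAlgError:
            continue
        if np.min(xb) < -1e-9:
            continue
        x = np.zeros(n)
        x[list(cols)] = np.maximum(xb, 0.0)
        val = float(v @ x)
        if val < best:
            best, bx = val, x
    return best, bx


def simplex_ls_support_enumeration(A, y):
    """Exact simplex-constrained least squares via KKT solves on every
    candidate active set (small p only)."""
    A = np.asarray(A, dtype=float)
    n, p = A.shape
    best, bx = np.inf, None
    for k in range(1, p + 1):
        for sup in itertools.combinations(range(p), k):
            S = list(sup)
            As = A[:, S]
            K = np.zeros((k + 1, k + 1))
            K[:k, :k] = As.T @ As
            K[:k, k] = 1.0
            K[k, :k] = 1.0
            rhs = np.concatenate([As.T @ y, [1.0]])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                continue
            xs = sol[:k]
            if xs.min() < -1e-9:
                continue
            x = np.zeros(p)
            x[S] = xs
            val = 0.5 * float(np.sum((y - A @ x) ** 2))
            if val < best:
                best, bx = val, x
    return best, bx


def soc_projection_oracle(inst):
    """Nearest point under ``‖Au + b‖ ≤ cᵗu + d`` by SLSQP from several starts."""
    A = np.asarray(inst.A, dtype=float)
    b, c, d, x = inst.b, inst.c, float(inst.d), inst.x

    def obj(u):
        return 0.5 * float(np.sum((x - u) ** 2))

    con = {"type": "ineq", "fun": lambda u: (c @ u + d) - np.linalg.norm(A @ u + b)}
    best = np.inf
    for u0 in [np.zeros_like(x), 0.5 * x, x]:
        res = minimize(obj, u0, constraints=[con], method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-14})
        if res.success or res.fun < best:
            best = min(best, float(res.fun))
    return best
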