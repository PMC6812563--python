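"""Projection operators: worked examples, invariants, and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from proxdistance.projections import (
    AffineProjector,
    kinship_structure_operator,
    nonnegative_operator,
    project_affine,
    project_complementarity,
    project_graph_manifold,
    project_kinship_structure,
    project_lorentz,
    project_nonnegative,
    project_psd,
    project_simplex,
    project_sparsity,
    project_sphere_nonneg,
    project_stiefel,
    prox_inequality_bisection,
    psd_operator,
    simplex_operator,
    sphere_nonneg_operator,
)

rng = np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------


class TestAffine:
    def test_point_on_set_is_fixed(self):
        A = rng.standard_normal((2, 5))
        x = rng.standard_normal(5)
        b = A @ x
        assert np.allclose(project_affine(A, b, x), x, atol=1e-10)

    def test_least_distance_kkt_example(self):
        # nearest point to the origin on x1 + x2 = 1 is (1/2, 1/2)
        out = project_affine(np.array([[1.0, 1.0]]), np.array([1.0]), np.zeros(2))
        assert np.allclose(out, [0.5, 0.5], atol=1e-12)

    def test_idempotent_and_feasible_on_random(self):
        A = rng.standard_normal((3, 7))
        b = rng.standard_normal(3)
        proj = AffineProjector(A, b)
        x = rng.standard_normal(7)
        p1 = proj.apply(x)
        assert np.linalg.norm(A @ p1 - b) < 1e-8
        assert np.allclose(proj.apply(p1), p1, atol=1e-10)

    def test_rank_deficient_rejected(self):
        A = np.array([[1.0, 2.0], [2.0, 4.0]])
        with pytest.raises(np.linalg.LinAlgError):
            AffineProjector(A, np.array([1.0, 2.0]))
        # and accepted with explicit truncation
        proj = AffineProjector(A, np.array([1.0, 2.0]), allow_rank_deficient=True)
        out = proj.apply(np.zeros(2))
        assert np.all(np.isfinite(out))


@pytest.mark.parametrize(
    "x, expected",
    [([1.0, 2.0], [1.0, 2.0]), ([-1.0, 2.0], [0.0, 2.0]), ([-3.0, -4.0], [0.0, 0.0])],
)
def test_nonnegative_examples(x, expected):
    assert np.allclose(project_nonnegative(np.array(x)), expected)


class TestSimplex:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([1.0, 0.0, 0.0], [1.0, 0.0, 0.0]),
            ([0.5, 0.5, 0.5], [1 / 3, 1 / 3, 1 / 3]),
            ([2.0, 0.0], [1.0, 0.0]),
        ],
    )
    def test_examples(self, x, expected):
        assert np.allclose(project_simplex(np.array(x)), expected, atol=1e-12)

    def test_against_support_enumeration(self):
        # exact KKT solve on every candidate support, dimension <= 4
        for _ in range(25):
            x = rng.standard_normal(4) * 2
            best, bx = np.inf, None
            for k in range(1, 5):
                for sup in itertools.combinations(range(4), k):
                    # equality-constrained least distance on the support
                    xs = x[list(sup)]
                    s = (np.sum(xs) - 1.0) / k
                    cand = xs - s
                    if cand.min() < -1e-12:
                        continue
                    full = np.zeros(4)
                    full[list(sup)] = cand
                    d = np.sum((full - x) ** 2)
                    if d < best:
                        best, bx = d, full
            assert np.allclose(project_simplex(x), bx, atol=1e-10)


class TestPSD:
    def test_identity_fixed(self):
        assert np.allclose(project_psd(np.eye(3)), np.eye(3))

    def test_diagonal_truncation(self):
        assert np.allclose(project_psd(np.diag([1.0, -1.0])), np.diag([1.0, 0.0]))

    def test_nearest_psd_oracle_3x3(self):
        # oracle: minimize ‖LLᵗ − X‖_F over lower-triangular L (any PSD matrix
        # is LLᵗ), from several starts
        for seed in range(3):
            r2 = np.random.default_rng(seed)
            X = r2.standard_normal((3, 3))
            X = 0.5 * (X + X.T)

            def obj(theta):
                L = np.zeros((3, 3))
                L[np.tril_indices(3)] = theta
                return np.sum((L @ L.T - X) ** 2)

            best = np.inf
            for _ in range(5):
                res = minimize(obj, r2.standard_normal(6), method="Nelder-Mead",
                               options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
                best = min(best, res.fun)
            ours = np.sum((project_psd(X) - X) ** 2)
            assert ours <= best + 1e-6

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            project_psd(np.array([[np.nan, 0.0], [0.0, 1.0]]))


class TestKinshipStructure:
    def test_valid_matrix_fixed(self):
        Y = np.array([[0.5, 0.1], [0.1, 0.5]])
        assert np.allclose(project_kinship_structure(Y), Y)

    def test_rule_application(self):
        Y = np.array([[0.3, -0.2], [-0.2, 0.9]])
        assert np.allclose(project_kinship_structure(Y), [[0.5, 0.0], [0.0, 0.5]])

    def test_idempotent(self):
        Y = rng.standard_normal((4, 4))
        P = project_kinship_structure(Y)
        assert np.allclose(project_kinship_structure(P), P)


class TestLorentz:
    def test_interior_fixed(self):
        w, r = project_lorentz(np.array([1.0, 0.0]), 2.0)
        assert np.allclose(w, [1.0, 0.0]) and r == 2.0

    def test_boundary_formula(self):
        w, r = project_lorentz(np.array([3.0, 4.0]), 0.0)
        assert np.allclose(w, [1.5, 2.0]) and np.isclose(r, 2.5)

    def test_polar_cone_to_apex(self):
        w, r = project_lorentz(np.array([0.0, 0.0]), -1.0)
        assert np.allclose(w, 0.0) and r == 0.0

    def test_oracle_3_variables(self):
        # constrained least distance solved numerically (SLSQP)
        for seed in range(6):
            r2 = np.random.default_rng(100 + seed)
            w0 = r2.standard_normal(2) * 2
            r0 = r2.standard_normal()

            def obj(z):
                return np.sum((z[:2] - w0) ** 2) + (z[2] - r0) ** 2

            con = {"type": "ineq", "fun": lambda z: z[2] - np.linalg.norm(z[:2])}
            res = minimize(obj, np.array([0.0, 0.0, 1.0]), constraints=[con],
                           method="SLSQP", options={"ftol": 1e-14, "maxiter": 300})
            w, r = project_lorentz(w0, r0)
            ours = np.sum((w - w0) ** 2) + (r - r0) ** 2
            assert ours <= res.fun + 1e-6


class TestSphereNonneg:
    @pytest.mark.parametrize(
        "y, expected",
        [
            ([3.0, 4.0], [0.6, 0.8]),
            ([3.0, -4.0], [1.0, 0.0]),
            ([-1.0, -2.0], [1.0, 0.0]),
            ([0.0, 0.0], [1.0, 0.0]),
        ],
    )
    def test_cases(self, y, expected):
        assert np.allclose(project_sphere_nonneg(np.array(y)), expected)

    def test_oracle_by_support_enumeration(self):
        # nearest point on {‖x‖=1, x ≥ 0}: for each support the optimum is the
        # normalized clamped restriction (or a coordinate vector)
        for _ in range(30):
            y = rng.standard_normal(4) * 1.5
            best, bx = np.inf, None
            for k in range(1, 5):
                for sup in itertools.combinations(range(4), k):
                    ys = np.maximum(y[list(sup)], 0.0)
                    if np.linalg.norm(ys) == 0:
                        cands = [np.eye(k)[i] for i in range(k)]
                    else:
                        cands = [ys / np.linalg.norm(ys)]
                    for c in cands:
                        full = np.zeros(4)
                        full[list(sup)] = c
                        d = np.sum((full - y) ** 2)
                        if d < best - 1e-12:
                            best, bx = d, full
            ours = project_sphere_nonneg(y)
            assert np.isclose(np.sum((ours - y) ** 2), best, atol=1e-9)


class TestComplementarity:
    @pytest.mark.parametrize(
        "u, v, ex, ey",
        [(2.0, 1.0, 2.0, 0.0), (1.0, 2.0, 0.0, 2.0), (-1.0, -1.0, 0.0, 0.0)],
    )
    def test_componentwise_rules(self, u, v, ex, ey):
        x, y = project_complementarity(np.array([u]), np.array([v]))
        assert x[0] == ex and y[0] == ey

    def test_output_is_complementary(self):
        u, v = rng.standard_normal(6), rng.standard_normal(6)
        x, y = project_complementarity(u, v)
        assert np.all(x >= 0) and np.all(y >= 0) and x @ y == 0.0

    def test_brute_force_oracle(self):
        # per component the three candidate pairs are exhaustive
        for _ in range(30):
            u, v = rng.standard_normal(3), rng.standard_normal(3)
            x, y = project_complementarity(u, v)
            ours = np.sum((x - u) ** 2 + (y - v) ** 2)
            best = 0.0
            for ui, vi in zip(u, v):
                cands = [(max(ui, 0.0), 0.0), (0.0, max(vi, 0.0)), (0.0, 0.0)]
                best += min((ci - ui) ** 2 + (di - vi) ** 2 for ci, di in cands)
            assert np.isclose(ours, best, atol=1e-12)


class TestSparsity:
    def test_column_example(self):
        out = project_sparsity(np.array([3.0, -5.0, 1.0]), 1)
        assert np.allclose(out, [0.0, -5.0, 0.0])

    def test_full_budget_unchanged(self):
        v = rng.standard_normal(5)
        assert np.allclose(project_sparsity(v, 5), v)

    def test_matrix_mode_oracle(self):
        U = np.array([[3.0, -5.0], [1.0, 0.0]])
        out = project_sparsity(U, 2, mode="matrix")
        assert np.allclose(out, [[3.0, -5.0], [0.0, 0.0]])
        # brute force over all 2-subsets of entries
        for _ in range(10):
            M = rng.standard_normal((2, 2))
            ours = project_sparsity(M, 2, mode="matrix")
            best = np.inf
            for sub in itertools.combinations(range(4), 2):
                cand = np.zeros(4)
                cand[list(sub)] = M.ravel()[list(sub)]
                best = min(best, np.sum((cand - M.ravel()) ** 2))
            assert np.isclose(np.sum((ours - M) ** 2), best, atol=1e-12)

    def test_tie_breaks_to_lowest_index(self):
        out = project_sparsity(np.array([2.0, -2.0, 2.0]), 1)
        assert np.allclose(out, [2.0, 0.0, 0.0])

    def test_invalid_budget(self):
        with pytest.raises(ValueError):
            project_sparsity(np.ones(3), 0)


class TestStiefel:
    def test_orthonormal_fixed(self):
        Q, _ = np.linalg.qr(rng.standard_normal((5, 2)))
        assert np.allclose(project_stiefel(Q), Q, atol=1e-10)

    def test_scalar_normalization(self):
        assert np.allclose(project_stiefel(np.array([[2.0]])), [[1.0]])

    def test_nearest_frame_oracle_4x2(self):
        # oracle minimization over orthonormal frames parametrized by QR
        U = np.random.default_rng(3).standard_normal((4, 2))

        def obj(theta):
            B = theta.reshape(4, 2)
            Q, R = np.linalg.qr(B)
            Q = Q * np.sign(np.diag(R))
            return np.sum((Q - U) ** 2)

        best = np.inf
        r2 = np.random.default_rng(4)
        for _ in range(20):
            res = minimize(obj, r2.standard_normal(8), method="Nelder-Mead",
                           options={"maxiter": 6000, "fatol": 1e-13, "xatol": 1e-10})
            best = min(best, res.fun)
        ours = np.sum((project_stiefel(U) - U) ** 2)
        assert ours <= best + 1e-6

    def test_result_orthonormal(self):
        U = rng.standard_normal((6, 3))
        P = project_stiefel(U)
        assert np.allclose(P.T @ P, np.eye(3), atol=1e-8)


class TestGraphManifold:
    def test_zero_matrix(self):
        u, v = rng.standard_normal(3), rng.standard_normal(2)
        x, y = project_graph_manifold(u, v, np.zeros((2, 3)))
        assert np.allclose(x, u) and np.allclose(y, 0.0)

    def test_scalar_line(self):
        x, y = project_graph_manifold(np.array([1.0]), np.array([3.0]), np.array([[1.0]]))
        assert np.isclose(x[0], 2.0) and np.isclose(y[0], 2.0)

    def test_woodbury_matches_direct(self):
        A = rng.standard_normal((3, 5))  # n < p triggers the Woodbury route
        u, v = rng.standard_normal(5), rng.standard_normal(3)
        x_w, y_w = project_graph_manifold(u, v, A)
        x_d = np.linalg.solve(np.eye(5) + A.T @ A, u + A.T @ v)
        assert np.allclose(x_w, x_d, atol=1e-10)
        assert np.allclose(y_w, A @ x_w, atol=1e-12)


class TestBisectionProx:
    def test_already_feasible(self):
        y = np.array([0.1, 0.2])
        out = prox_inequality_bisection(
            lambda lam, z: z / (1 + lam), np.linalg.norm, 1.0, y
        )
        assert np.allclose(out, y)

    def test_unit_ball_projection(self):
        # a(x) = ‖x‖ has prox_{λa}(y) = (1 − λ/‖y‖)₊ y
        def prox_norm(lam, z):
            nz = np.linalg.norm(z)
            return max(0.0, 1 - lam / nz) * z if nz > 0 else z

        out = prox_inequality_bisection(prox_norm, np.linalg.norm, 1.0, np.array([3.0, 4.0]), tol=1e-12)
        assert np.allclose(out, [0.6, 0.8], atol=1e-9)

    def test_linear_constraint(self):
        # a(x) = x, prox_{λa}(y) = y − λ; stationarity forces x = t
        out = prox_inequality_bisection(
            lambda lam, z: z - lam, lambda z: float(z), 0.0, np.array(2.0), tol=1e-12
        )
        assert abs(float(out)) <= 1e-9


# ---------------------------------------------------------------------------
# Invariants (property tests)
# ---------------------------------------------------------------------------

_OPERATORS = {
    "nonnegative": nonnegative_operator,
    "simplex": simplex_operator,
    "psd": psd_operator,
    "kinship": kinship_structure_operator,
    "sphere_nonneg": sphere_nonneg_operator,
}
_CONVEX = ["nonnegative", "simplex", "psd", "kinship"]


def _random_point(name, r):
    if name == "psd" or name == "kinship":
        M = r.standard_normal((3, 3))
        return 0.5 * (M + M.T)
    return r.standard_normal(4) * 2


@pytest.mark.parametrize("name", list(_OPERATORS))
def test_idempotence(name):
    op = _OPERATORS[name]
    r = np.random.default_rng(11)
    for _ in range(20):
        x = _random_point(name, r)
        p = op.apply(x)
        assert np.linalg.norm(np.ravel(op.apply(p) - p)) < 1e-10


@pytest.mark.parametrize("name", _CONVEX)
def test_nonexpansiveness_convex(name):
    op = _OPERATORS[name]
    r = np.random.default_rng(12)
    for _ in range(30):
        x, y = _random_point(name, r), _random_point(name, r)
        lhs = np.linalg.norm(np.ravel(op.apply(x) - op.apply(y)))
        rhs = np.linalg.norm(np.ravel(x - y))
        assert lhs <= rhs + 1e-10


@pytest.mark.parametrize("name", list(_OPERATORS))
def test_gradient_identity(name):
    # ∇ ½dist(x, C)² = x − P_C(x) wherever the projection is single valued
    op = _OPERATORS[name]
    r = np.random.default_rng(13)
    for _ in range(5):
        x = _random_point(name, r)
        flat = np.ravel(x).copy()

        def half_dist_sq(f):
            return 0.5 * op.distance(f.reshape(np.shape(x))) ** 2

        grad = np.zeros_like(flat)
        h = 1e-6
        for i in range(flat.size):
            e = np.zeros_like(flat)
            e[i] = h
            grad[i] = (half_dist_sq(flat + e) - half_dist_sq(flat - e)) / (2 * h)
        expected = flat - np.ravel(op.apply(x))
        assert np.allclose(grad, expected, atol=1e-5)


@given(st.lists(st.floats(-5, 5), min_size=2, max_size=4))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_simplex_output_is_on_simplex(vals):
    p = project_simplex(np.array(vals))
    assert p.min() >= 0
    assert np.isclose(p.sum(), 1.0, atol=1e-10)


@given(st.lists(st.floats(-5, 5), min_size=2, max_size=5), st.floats(-5, 5))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_lorentz_output_in_cone(wvals, r0):
    w, r = project_lorentz(np.array(wvals), r0)
    assert np.linalg.norm(w) <= r + 1e-9
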