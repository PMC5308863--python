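"""ISTA solver: shrinkage operator, step size, oracle agreement, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from sparsepitch import sparse_coder as sc


class TestSoftThreshold:
    @pytest.mark.parametrize("x, t, expected", [
        (0.5, 0.2, 0.3),
        (-0.5, 0.2, -0.3),
        (0.1, 0.2, 0.0),
    ])
    def test_closed_form(self, x, t, expected):
        assert sc.soft_threshold(x, t) == pytest.approx(expected, abs=1e-15)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            sc.soft_threshold(1.0, -0.1)

    @given(hnp.arrays(np.float64, 10,
                      elements=st.floats(-100, 100)),
           st.floats(0, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shrinkage_properties(self, x, t):
        y = sc.soft_threshold(x, t)
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)
        assert np.all((y == 0) | (np.sign(y) == np.sign(x)))
        assert np.all(np.abs(y[np.abs(x) > t] - x[np.abs(x) > t])
                      <= t + 1e-12)


class TestEstimateStep:
    def test_orthonormal_columns(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((30, 10)))
        assert sc.estimate_step(q) == pytest.approx(1.05, rel=1e-6)

    def test_scaling(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((30, 10)))
        assert sc.estimate_step(3.0 * q) == pytest.approx(1.05 * 9.0, rel=1e-6)

    def test_against_dense_eigensolver(self, rng):
        D = rng.standard_normal((50, 10))
        top = np.linalg.eigvalsh(D.T @ D)[-1]
        assert sc.estimate_step(D) == pytest.approx(1.05 * top, rel=0.01)


def cd_lasso_objective(v, D, lam):
    """Independent coordinate-descent oracle for
    0.5*||v - D h||^2 + (lam/2)*||h||_1 (sklearn's CD solver, rescaled)."""
    from sklearn.linear_model import Lasso

    n = len(v)
    model = Lasso(alpha=lam / (2 * n), fit_intercept=False, tol=1e-14,
                  max_iter=200_000)
    model.fit(D, v)
    h = model.coef_
    return 0.5 * np.sum((v - D @ h) ** 2) + 0.5 * lam * np.abs(h).sum(), h


class TestSolve:
    def test_single_atom_fixed_point(self):
        # orthonormal single atom: the minimiser is c - lam/2, independent
        # of the step size
        d = np.zeros((5, 1))
        d[0, 0] = 1.0
        c = 0.8
        code = sc.solve(c * d[:, 0], d,
                        sc.SolverConfig(lam=0.01, tol=1e-14, max_iter=10_000))
        assert code.h[0] == pytest.approx(c - 0.005, abs=1e-8)

    def test_zero_input(self, rng):
        D = rng.standard_normal((20, 5))
        code = sc.solve(np.zeros(20), D, sc.SolverConfig(lam=0.01))
        assert np.all(code.h == 0)
        assert code.objective == pytest.approx(0.0, abs=1e-30)

    def test_matches_coordinate_descent_oracle(self, rng):
        for _ in range(20):
            rows = int(rng.integers(20, 101))
            cols = int(rng.integers(3, 21))
            D = rng.standard_normal((rows, cols))
            D /= np.linalg.norm(D, axis=0)
            v = D @ rng.standard_normal(cols) + 0.1 * rng.standard_normal(rows)
            code = sc.solve(v, D, sc.SolverConfig(lam=0.01, tol=1e-13,
                                                  max_iter=100_000))
            ref_obj, _ = cd_lasso_objective(v, D, 0.01)
            assert code.objective == pytest.approx(ref_obj, rel=1e-6, abs=1e-12)

    def test_lambda_zero_reaches_least_squares(self, rng):
        D = rng.standard_normal((40, 8))
        v = rng.standard_normal(40)
        code = sc.solve(v, D, sc.SolverConfig(lam=0.0, tol=1e-12,
                                              max_iter=100_000))
        h_ls, *_ = np.linalg.lstsq(D, v, rcond=None)
        # exit clamp zeroes negative weights; compare the clamped reference
        assert code.h == pytest.approx(np.maximum(h_ls, 0.0), abs=1e-5)

    def test_sparsity_increases_with_lambda(self, rng):
        D = rng.standard_normal((100, 20))
        D /= np.linalg.norm(D, axis=0)
        v = D @ np.concatenate([rng.uniform(0.5, 1, 4), np.zeros(16)]) \
            + 0.05 * rng.standard_normal(100)
        nnz = []
        for lam in (0.01, 0.001, 0.0):
            code = sc.solve(v, D, sc.SolverConfig(lam=lam, tol=1e-12,
                                                  max_iter=100_000))
            nnz.append(int(np.sum(np.abs(code.h_grouped) > 1e-10)))
        assert nnz[0] <= nnz[1] <= nnz[2]

    def test_objective_monotone_descent(self, rng):
        D = rng.standard_normal((60, 12))
        v = rng.standard_normal(60)
        code = sc.solve(v, D, sc.SolverConfig(lam=0.01, record_trace=True,
                                              max_iter=2000))
        diffs = np.diff(code.trace)
        assert np.all(diffs <= 1e-12 * np.maximum(np.abs(code.trace[:-1]), 1.0))

    def test_support_recovery_at_40db_snr(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((200, 30)))
        truth = [3, 15, 27]
        v = q[:, truth] @ np.array([1.0, 0.8, 0.6])
        noise = rng.standard_normal(200)
        v = v + noise * (np.linalg.norm(v) / np.linalg.norm(noise)) * 10 ** (-40 / 20)
        code = sc.solve(v, q, sc.SolverConfig(lam=0.01, tol=1e-12,
                                              max_iter=50_000))
        top3 = np.argsort(code.h)[::-1][:3]
        assert set(top3) == set(truth)

    def test_gram_update_equals_direct_ista(self, rng):
        """The Gram-matrix inner loop reproduces the direct ISTA update."""
        D = rng.standard_normal((30, 6))
        v = rng.standard_normal(30)
        lam, n_iter = 0.01, 300
        alpha = sc.estimate_step(D)
        h = np.zeros(6)
        for _ in range(n_iter):
            h = sc.soft_threshold(h + D.T @ (v - D @ h) / alpha,
                                  lam / (2 * alpha))
        code = sc.solve(v, D, sc.SolverConfig(lam=lam, tol=0.0,
                                              max_iter=n_iter))
        # identical up to float non-associativity of the two update orderings
        assert code.h_grouped == pytest.approx(np.maximum(h, 0.0), abs=1e-6)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            sc.solve(np.ones(7), rng.standard_normal((6, 3)))


class TestCollapseGroups:
    def test_identity_for_single_group(self):
        h = np.array([0.1, 0.2, 0.3])
        assert np.array_equal(sc.collapse_groups(h, 1), h)

    def test_group_sum(self):
        h = np.array([0.2, 0.3, 0.0, 1.0, 0.0, 0.5])
        assert sc.collapse_groups(h, 3) == pytest.approx([0.5, 1.5])

    def test_all_zero(self):
        assert np.all(sc.collapse_groups(np.zeros(6), 2) == 0)

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sc.collapse_groups(np.zeros(7), 2)
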