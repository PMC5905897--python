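"""Update solvers: Tikhonov, IRLS, ADMM, FISTA against independent oracles.

Convention reminder: the L1 solvers implement their printed updates, whose
effective L1 weight relative to ``||r||^2 + lam ||x||_1`` is ``2 lam``;
oracle comparisons therefore pass ``lam/2`` to the solvers.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import scdot as sd
from scdot.errors import DimensionError, NumericalError, ParameterError

from .oracles import lasso_objective, lasso_oracle


def random_problem(rng, m=10, n=8, lam_frac=0.1):
    J = rng.standard_normal((m, n))
    y = rng.standard_normal(m)
    lam = lam_frac * np.abs(2.0 * J.T @ y).max()
    return J, y, lam


class TestTikhonov:
    def test_identity_system(self):
        res = sd.tikhonov_update(sd.UpdateProblem(np.eye(2), np.array([1.0, 1.0]), 1.0))
        assert np.allclose(res.delta_c, [0.5, 0.5])

    def test_orthonormal_zero_lambda(self):
        # a 3x3 rotation is orthonormal: the solution is J^T y
        th = 0.3
        J = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        y = np.array([1.0, -2.0, 0.5])
        res = sd.tikhonov_update(sd.UpdateProblem(J, y, 0.0))
        assert np.allclose(res.delta_c, J.T @ y, atol=1e-12)

    def test_matches_augmented_least_squares(self):
        rng = np.random.default_rng(10)
        J, y, lam = random_problem(rng, 10, 8)
        res = sd.tikhonov_update(sd.UpdateProblem(J, y, lam))
        stacked = np.vstack([J, np.sqrt(lam) * np.eye(8)])
        rhs = np.concatenate([y, np.zeros(8)])
        expected, *_ = np.linalg.lstsq(stacked, rhs, rcond=None)
        assert np.allclose(res.delta_c, expected, atol=1e-10)

    def test_singular_at_zero_lambda_raises(self):
        J = np.zeros((3, 2))
        J[:, 0] = [1.0, 2.0, 3.0]  # rank deficient
        with pytest.raises(NumericalError):
            sd.tikhonov_update(sd.UpdateProblem(J, np.ones(3), 0.0))

    def test_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(11)
        J, y, _ = random_problem(rng, 12, 8)
        norms = [
            np.linalg.norm(sd.tikhonov_update(sd.UpdateProblem(J, y, lam)).delta_c)
            for lam in (0.01, 0.1, 1.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))


class TestIrlsWeights:
    def test_above_floor_uses_inverse_sqrt(self):
        assert sd.irls_weights(np.array([0.04]), 0.01)[0] == pytest.approx(5.0)

    def test_below_floor_uses_inverse_epsilon(self):
        assert sd.irls_weights(np.array([0.001]), 0.01)[0] == pytest.approx(100.0)

    def test_unit_update_gives_unit_weight(self):
        assert sd.irls_weights(np.array([1.0]), 0.01)[0] == pytest.approx(1.0)

    @given(
        hnp.arrays(np.float64, st.integers(1, 20), elements=st.floats(-10, 10)),
        st.floats(1e-4, 0.99),
    )
    def test_weights_positive_and_capped(self, dc, eps):
        w = sd.irls_weights(dc, eps)
        assert (w > 0).all()
        assert (w <= 1.0 / eps + 1e-12).all()


class TestIrls:
    def test_unit_weights_reproduce_tikhonov_exactly(self):
        rng = np.random.default_rng(12)
        J, y, lam = random_problem(rng)
        problem = sd.UpdateProblem(J, y, lam)
        tik = sd.tikhonov_update(problem).delta_c
        irls = sd.irls_solve(
            problem,
            sd.SolverSettings(method="irls", force_unit_weights=True, max_inner_iter=1),
        ).delta_c
        assert np.array_equal(irls, tik) or np.allclose(irls, tik, rtol=0, atol=1e-16)

    def test_zero_lambda_reaches_least_squares(self):
        rng = np.random.default_rng(13)
        J, y, _ = random_problem(rng, 12, 6)
        res = sd.irls_solve(sd.UpdateProblem(J, y, 0.0))
        expected, *_ = np.linalg.lstsq(J, y, rcond=None)
        assert np.allclose(res.delta_c, expected, atol=1e-8)

    def test_fixed_point_near_lasso_optimum(self):
        rng = np.random.default_rng(14)
        J, y, lam = random_problem(rng, 8, 6)
        x_star = lasso_oracle(J, y, lam)
        f_star = lasso_objective(J, y, lam, x_star)
        res = sd.irls_solve(
            sd.UpdateProblem(J, y, lam / 2.0),  # convention mapping
            sd.SolverSettings(method="irls", epsilon_irls=0.001, tol=1e-12,
                              max_inner_iter=200),
        )
        f = lasso_objective(J, y, lam, res.delta_c)
        assert (f - f_star) / abs(f_star) < 1e-3


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x,tau,expected", [(0.5, 1.0, 0.0), (2.0, 0.5, 1.5), (-3.0, 1.0, -2.0)]
    )
    def test_examples(self, x, tau, expected):
        assert sd.soft_threshold(np.array([x]), tau)[0] == pytest.approx(expected)

    def test_negative_threshold_raises(self):
        with pytest.raises(ParameterError):
            sd.soft_threshold(np.array([1.0]), -0.1)

    @given(
        hnp.arrays(np.float64, st.integers(1, 30), elements=st.floats(-100, 100)),
        st.floats(0, 50),
    )
    def test_shrinkage_properties(self, x, tau):
        out = sd.soft_threshold(x, tau)
        assert np.all(np.abs(out) <= np.maximum(np.abs(x) - tau, 0) + 1e-12)
        assert np.all(out[np.abs(x) <= tau] == 0)
        nz = np.abs(x) > tau
        assert np.all(np.sign(out[nz]) == np.sign(x[nz]))


class TestAdmm:
    def test_zero_lambda_reaches_least_squares(self):
        rng = np.random.default_rng(15)
        J, y, _ = random_problem(rng, 12, 6)
        res = sd.admm_solve(
            sd.UpdateProblem(J, y, 0.0),
            sd.SolverSettings(method="admm", tol=1e-12, max_inner_iter=2000),
        )
        expected, *_ = np.linalg.lstsq(J, y, rcond=None)
        assert np.allclose(res.delta_c, expected, atol=1e-6)

    def test_large_lambda_gives_zero_solution(self):
        rng = np.random.default_rng(16)
        J, y, _ = random_problem(rng)
        lam_zero = np.abs(2.0 * J.T @ y).max()  # oracle zero-solution threshold
        x_star = lasso_oracle(J, y, 1.5 * lam_zero)
        assert np.allclose(x_star, 0)
        res = sd.admm_solve(
            sd.UpdateProblem(J, y, 1.5 * lam_zero / 2.0),
            sd.SolverSettings(method="admm", tol=1e-10, max_inner_iter=2000),
        )
        assert np.abs(res.delta_c).max() < 1e-8

    def test_objective_near_lasso_optimum(self):
        rng = np.random.default_rng(17)
        J, y, lam = random_problem(rng, 8, 6)
        x_star = lasso_oracle(J, y, lam)
        f_star = lasso_objective(J, y, lam, x_star)
        res = sd.admm_solve(
            sd.UpdateProblem(J, y, lam / 2.0),
            sd.SolverSettings(method="admm", tol=1e-12, max_inner_iter=5000),
        )
        f = lasso_objective(J, y, lam, res.delta_c)
        assert (f - f_star) / abs(f_star) < 1e-3


class TestStepEstimate:
    def test_orthonormal_unit_spectrum(self):
        assert sd.lipschitz_constant(np.eye(5)) == pytest.approx(1.0, rel=1e-3)
        assert sd.estimate_step(np.eye(5)) == pytest.approx(0.9, rel=1e-3)

    def test_scaled_identity(self):
        assert sd.lipschitz_constant(2.0 * np.eye(4)) == pytest.approx(4.0, rel=1e-3)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(18)
        J = rng.standard_normal((20, 10))
        expected = np.linalg.eigvalsh(J.T @ J)[-1]
        assert sd.lipschitz_constant(J) == pytest.approx(expected, rel=1e-3)

    def test_zero_matrix_raises(self):
        with pytest.raises(ParameterError):
            sd.estimate_step(np.zeros((3, 3)))


class TestFista:
    def test_zero_lambda_reaches_least_squares(self):
        rng = np.random.default_rng(19)
        J, y, _ = random_problem(rng, 12, 6)
        res = sd.fista_solve(
            sd.UpdateProblem(J, y, 0.0),
            sd.SolverSettings(method="fista", tol=1e-12, max_inner_iter=5000),
        )
        expected, *_ = np.linalg.lstsq(J, y, rcond=None)
        assert np.allclose(res.delta_c, expected, atol=1e-6)

    def test_above_threshold_shrinks_to_zero(self):
        rng = np.random.default_rng(20)
        J, y, _ = random_problem(rng)
        lam_zero = np.abs(2.0 * J.T @ y).max()
        res = sd.fista_solve(
            sd.UpdateProblem(J, y, 1.5 * lam_zero / 2.0),
            sd.SolverSettings(method="fista", tol=1e-12, max_inner_iter=2000),
        )
        assert np.abs(res.delta_c).max() < 1e-10

    def test_invalid_step_without_backtracking_raises(self):
        J = np.eye(3)
        with pytest.raises(ParameterError):
            sd.fista_solve(
                sd.UpdateProblem(J, np.ones(3), 0.1),
                sd.SolverSettings(method="fista", step_t=2.0, backtracking=False),
            )

    def test_running_best_objective_nonincreasing(self):
        rng = np.random.default_rng(21)
        J, y, lam = random_problem(rng, 15, 10)
        res = sd.fista_solve(
            sd.UpdateProblem(J, y, lam), sd.SolverSettings(method="fista")
        )
        best = np.minimum.accumulate(res.objective_trace)
        assert np.all(np.diff(best) <= 1e-12)

    def test_ista_mode_strictly_monotone(self):
        rng = np.random.default_rng(22)
        J, y, lam = random_problem(rng, 15, 10)
        res = sd.fista_solve(
            sd.UpdateProblem(J, y, lam),
            sd.SolverSettings(method="fista", momentum=False, max_inner_iter=100),
        )
        assert np.all(np.diff(res.objective_trace) <= 1e-12)


@pytest.mark.parametrize("method", ["fista", "admm"])
def test_sparsity_nondecreasing_along_lambda_ladder(method):
    rng = np.random.default_rng(23)
    J = rng.standard_normal((12, 9))
    y = rng.standard_normal(12)
    lam_max = np.abs(J.T @ y).max()
    settings = sd.SolverSettings(method=method, tol=1e-12, max_inner_iter=5000)
    zeros = []
    for lam in lam_max * 10.0 ** -np.linspace(0, 3, 10):
        solver = sd.fista_solve if method == "fista" else sd.admm_solve
        x = solver(sd.UpdateProblem(J, y, lam), settings).delta_c
        zeros.append(int(np.sum(x == 0.0)))
    assert all(a >= b for a, b in zip(zeros, zeros[1:]))


@pytest.mark.parametrize("method", ["tikhonov", "irls", "admm", "fista"])
def test_zero_mismatch_gives_zero_update(method):
    problem = sd.UpdateProblem(np.eye(4), np.zeros(4), 0.5)
    res = sd.solve_update(problem, sd.SolverSettings(method=method))
    assert np.all(res.delta_c == 0)


def test_dimension_mismatch_rejected():
    with pytest.raises(DimensionError):
        sd.UpdateProblem(np.ones((3, 2)), np.ones(4), 0.1)
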