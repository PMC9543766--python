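"""SMO solver correctness against a brute-force QP oracle and by its KKT laws.

The oracle solves the same box-and-equality-constrained dual with
scipy.optimize (SLSQP) on the 2n-variable formulation; it was written before
the SMO solver and shares no code with it beyond the Gram matrix.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from mixsvr.kernels import KernelSpec, gram_matrix
from mixsvr.svr import (AdmissibilityError, SolverConfig, SVRModel,
                        SVRProblem, compute_bias, dual_objective,
                        kkt_violation, predict, solve_dual)

TIGHT = SolverConfig(kkt_tol=1e-8)


# ---------------------------------------------------------------------------
# independent QP oracle

def qp_oracle(problem: SVRProblem):
    """Maximize the SVR dual with SLSQP; returns (theta, objective, bias)."""
    n = problem.n
    K = gram_matrix(problem.kernel, problem.X).values
    y, eps, C = problem.y, problem.epsilon, problem.C

    def neg_dual(u):
        th = u[:n] - u[n:]
        return -(y @ th - eps * u.sum() - 0.5 * th @ K @ th)

    def grad(u):
        th = u[:n] - u[n:]
        kth = K @ th
        return -np.concatenate([y - eps - kth, -y - eps + kth])

    cons = {"type": "eq", "fun": lambda u: u[:n].sum() - u[n:].sum(),
            "jac": lambda u: np.concatenate([np.ones(n), -np.ones(n)])}
    res = minimize(neg_dual, np.zeros(2 * n), jac=grad, method="SLSQP",
                   bounds=[(0.0, C)] * (2 * n), constraints=[cons],
                   options={"maxiter": 1000, "ftol": 1e-14})
    u = res.x
    theta = u[:n] - u[n:]
    obj = -neg_dual(u)
    # oracle bias from the KKT boundary conditions of free coefficients
    tol = 1e-6 * C
    kth = K @ theta
    cands = []
    for i in range(n):
        if tol < theta[i] < C - tol:
            cands.append(y[i] - kth[i] - eps)
        elif -C + tol > theta[i] > -C + 0:  # pragma: no cover
            pass
        elif -(C - tol) < theta[i] < -tol:
            cands.append(y[i] - kth[i] + eps)
    bias = float(np.mean(cands)) if cands else None
    return theta, float(obj), bias


def random_problem(rng, kernel_kind):
    n = int(rng.integers(4, 21))
    d = int(rng.integers(1, 5))
    X = rng.normal(size=(n, d))
    y = rng.normal(scale=2.0, size=n) + X[:, 0]
    C = float(rng.choice([0.5, 2.0, 10.0]))
    eps = float(rng.choice([0.0, 0.1, 0.5]))
    kernels = {
        "rbf": KernelSpec(kind="rbf", gamma=1.0 / d),
        "poly": KernelSpec(kind="poly", sigma=1.0 / d, p=2),
        "linear_raw": KernelSpec(kind="linear_raw"),
        "sum_mixture": KernelSpec(kind="sum_mixture", gamma=1.0 / d,
                                  sigma=1.0 / d, p=2, beta=0.8),
        "product_mixture": KernelSpec(kind="product_mixture", gamma=1.0 / d,
                                      sigma=1.0 / d, p=2),
    }
    return SVRProblem(X, y, C=C, epsilon=eps, kernel=kernels[kernel_kind])


# ---------------------------------------------------------------------------
# hand-solvable fixture: two 1-D points, linear kernel

@pytest.fixture()
def fixture_1d():
    return SVRProblem(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]),
                      C=10.0, epsilon=0.1, kernel=KernelSpec(kind="linear_raw"))


def test_hand_fixture_recovers_flattest_interpolant(fixture_1d):
    """The flattest function threading both epsilon-tubes is 0.8x + 0.1."""
    model = solve_dual(fixture_1d, TIGHT)
    assert model.theta == pytest.approx([-0.8, 0.8], abs=1e-9)
    assert model.bias == pytest.approx(0.1, abs=1e-9)
    assert model.diagnostics.dual_objective == pytest.approx(0.32, abs=1e-9)
    assert predict(model, [[0.5]]) == pytest.approx([0.5], abs=1e-9)
    assert dual_objective(model, fixture_1d) == pytest.approx(0.32, abs=1e-9)


def test_constant_targets_give_zero_coefficients_and_bias_c():
    problem = SVRProblem(np.linspace(0, 1, 7)[:, None], np.full(7, 3.5),
                         C=4.0, epsilon=0.1,
                         kernel=KernelSpec(kind="rbf", gamma=1.0))
    model = solve_dual(problem, TIGHT)
    assert np.allclose(model.theta, 0.0)
    assert abs(model.bias - 3.5) <= 0.1 + 1e-12
    assert np.all(np.abs(predict(model, problem.X) - 3.5) <= 0.1 + 1e-9)


def test_zero_coefficient_model_predicts_bias_everywhere(fixture_1d):
    model = SVRModel(theta=np.zeros(2), alpha=np.zeros(2),
                     alpha_star=np.zeros(2), bias=0.4,
                     support_indices=np.array([], dtype=int),
                     kernel=fixture_1d.kernel, X_train=fixture_1d.X)
    assert np.allclose(predict(model, [[0.0], [7.0]]), 0.4)
    assert dual_objective(model, fixture_1d) == 0.0


def test_kkt_violation_flags_perturbed_and_trivial_models(fixture_1d):
    good = solve_dual(fixture_1d, TIGHT)
    assert kkt_violation(good, fixture_1d) <= 1e-8

    broken = SVRModel(theta=np.array([-0.8, 0.9]), alpha=np.array([0.8, 0.0]),
                      alpha_star=np.array([0.0, 0.9]), bias=0.1,
                      support_indices=np.array([0, 1]),
                      kernel=fixture_1d.kernel, X_train=fixture_1d.X)
    assert kkt_violation(broken, fixture_1d) >= 0.1 - 1e-9  # equality broken

    lazy = SVRModel(theta=np.zeros(2), alpha=np.zeros(2),
                    alpha_star=np.zeros(2), bias=0.5,
                    support_indices=np.array([], dtype=int),
                    kernel=fixture_1d.kernel, X_train=fixture_1d.X)
    assert kkt_violation(lazy, fixture_1d) > 0.0  # x=1 outside tube, theta=0


def test_compute_bias_agrees_with_oracle_on_random_problems(rng):
    for _ in range(10):
        problem = random_problem(rng, "rbf")
        model = solve_dual(problem, TIGHT)
        _, _, oracle_bias = qp_oracle(problem)
        if oracle_bias is not None and model.support_indices.size:
            free = np.abs(model.theta[model.support_indices])
            if np.any((free > 1e-6) & (free < problem.C - 1e-6)):
                assert model.bias == pytest.approx(oracle_bias, abs=1e-4)


def test_bias_midpoint_rule_for_constant_targets():
    problem = SVRProblem(np.array([[0.0], [1.0]]), np.array([2.0, 2.0]),
                         C=1.0, epsilon=0.3,
                         kernel=KernelSpec(kind="rbf", gamma=1.0))
    K = gram_matrix(problem.kernel, problem.X).values
    assert compute_bias(np.zeros(2), problem, K) == pytest.approx(2.0)


@pytest.mark.parametrize("kind", ["rbf", "poly", "linear_raw", "sum_mixture",
                                  "product_mixture"])
def test_dual_objective_matches_qp_oracle(kind, rng):
    """SMO reaches the same optimum as a generic QP solver (10 problems per
    kernel kind, 50 total)."""
    for _ in range(10):
        problem = random_problem(rng, kind)
        model = solve_dual(problem, TIGHT)
        _, oracle_obj, _ = qp_oracle(problem)
        assert model.diagnostics.dual_objective >= oracle_obj - 1e-6
        assert abs(model.diagnostics.dual_objective - oracle_obj) <= 1e-6
        # feasibility of the returned coefficients
        assert np.all(np.abs(model.theta) <= problem.C + 1e-9)
        assert abs(model.theta.sum()) <= 1e-8
        assert np.all(model.alpha * model.alpha_star == 0.0)


def test_predictions_match_oracle_predictions(rng):
    for _ in range(8):
        problem = random_problem(rng, "product_mixture")
        model = solve_dual(problem, TIGHT)
        theta_o, _, bias_o = qp_oracle(problem)
        if bias_o is None:
            continue
        Xnew = rng.normal(size=(5, problem.X.shape[1]))
        K = gram_matrix(problem.kernel, problem.X, Xnew).values
        assert np.allclose(model.predict(Xnew), K.T @ theta_o + bias_o,
                           atol=1e-4)


def test_interior_points_lie_inside_the_tube(rng):
    for _ in range(5):
        problem = random_problem(rng, "rbf")
        model = solve_dual(problem, TIGHT)
        resid = problem.y - model.predict(problem.X)
        inside = np.abs(model.theta) <= model.sv_tol
        assert np.all(np.abs(resid[inside]) <= problem.epsilon + 1e-6)


def test_removing_non_support_rows_leaves_predictions_unchanged(rng):
    problem = random_problem(rng, "rbf")
    model = solve_dual(problem, TIGHT)
    sv = model.support_indices
    trimmed = SVRModel(theta=model.theta[sv], alpha=model.alpha[sv],
                       alpha_star=model.alpha_star[sv], bias=model.bias,
                       support_indices=np.arange(sv.size),
                       kernel=model.kernel, X_train=model.X_train[sv])
    Xnew = np.random.default_rng(0).normal(size=(6, problem.X.shape[1]))
    assert np.allclose(model.predict(Xnew), trimmed.predict(Xnew), atol=1e-12)


def test_training_loss_non_increasing_in_C(rng):
    X = rng.normal(size=(25, 2))
    y = np.sin(X[:, 0]) + 0.3 * rng.normal(size=25)
    kernel = KernelSpec(kind="rbf", gamma=0.5)
    losses = []
    for C in (0.1, 1.0, 10.0, 100.0):
        model = solve_dual(SVRProblem(X, y, C=C, epsilon=0.1, kernel=kernel),
                           TIGHT)
        losses.append(model.diagnostics.slack.sum()
                      + model.diagnostics.slack_star.sum())
    assert all(a >= b - 1e-6 for a, b in zip(losses, losses[1:]))


def test_solver_is_deterministic(rng):
    problem = random_problem(rng, "sum_mixture")
    a = solve_dual(problem, SolverConfig(kkt_tol=1e-5, seed=1))
    b = solve_dual(problem, SolverConfig(kkt_tol=1e-5, seed=1))
    assert np.array_equal(a.theta, b.theta)
    assert a.bias == b.bias


def test_inadmissible_kernel_is_refused():
    problem = SVRProblem(np.array([[0.0], [1.0], [2.0]]),
                         np.array([0.0, 1.0, 2.0]), C=1.0, epsilon=0.1,
                         kernel=KernelSpec(kind="literal_rbf", gamma=1.0))
    with pytest.raises(AdmissibilityError):
        solve_dual(problem)


def test_invalid_problems_are_rejected():
    X, y = np.zeros((2, 1)), np.zeros(2)
    k = KernelSpec(kind="linear_raw")
    with pytest.raises(ValueError):
        SVRProblem(X, y, C=0.0, epsilon=0.1, kernel=k)
    with pytest.raises(ValueError):
        SVRProblem(X, y, C=1.0, epsilon=-0.1, kernel=k)
    with pytest.raises(ValueError):
        SVRProblem(X, np.array([np.nan, 0.0]), C=1.0, epsilon=0.1, kernel=k)
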