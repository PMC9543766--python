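"""Epsilon-insensitive support vector regression via SMO on the dual.

Given training pairs (x_i, y_i), i = 1..n, a box constraint C > 0, a tube
half-width epsilon >= 0 and an admissible kernel K, the fitted function is

    f(x) = sum_i theta_i K(x_i, x) + b,        theta_i = alpha*_i - alpha_i,

where (alpha, alpha*) maximize the dual

    sum_i y_i theta_i - epsilon sum_i (alpha_i + alpha*_i)
        - 1/2 sum_ij theta_i theta_j K(x_i, x_j)

subject to sum_i theta_i = 0 and 0 <= alpha_i, alpha*_i <= C.  Only points on
or outside the epsilon-tube end up with nonzero theta (support vectors); the
fitted function depends on those alone.

The solver is sequential minimal optimization (SMO) with maximal-violating-
pair working-set selection on the 2n-variable dual.  The convergence measure
is the KKT gap m - M between the largest and smallest feasible values of the
implied bias; at the optimum the gap is zero and any value in [M, m] is a
valid bias.  No shrinking or approximation is used, so the answer matches a
generic QP solver to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kernels import KernelSpec, gram_matrix

__all__ = [
    "SVRProblem",
    "SVRModel",
    "SolverConfig",
    "SolverDiagnostics",
    "ConvergenceError",
    "AdmissibilityError",
    "BiasError",
    "solve_dual",
    "dual_objective",
    "kkt_violation",
    "predict",
    "compute_bias",
]

#: full Gram matrices are precomputed up to this many training rows
FULL_CACHE_LIMIT = 10_000


class ConvergenceError(RuntimeError):
    """SMO did not reach the KKT tolerance within the iteration budget."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class AdmissibilityError(ValueError):
    """The kernel is not positive semidefinite; the dual is not concave."""


class BiasError(RuntimeError):
    """No feasible bias interval could be recovered from the KKT conditions."""


@dataclass
class SVRProblem:
    """One epsilon-SVR training problem."""

    X: np.ndarray
    y: np.ndarray
    C: float
    epsilon: float
    kernel: KernelSpec

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]}")
        if self.X.shape[0] < 1:
            raise ValueError("need at least one training point")
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be nonnegative, got {self.epsilon}")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite entries in X or y")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class SolverConfig:
    """SMO settings.

    kkt_tol is on the scale of the targets (UPDRS points here); max_iter
    defaults to 1e5 * n.  The seed is part of the interface for tie-breaking
    among equally violating pairs; selection is deterministic (first index),
    so results are reproducible regardless.
    """

    kkt_tol: float = 1e-3
    max_iter: Optional[int] = None
    cache_mode: str = "auto"  # auto | full  (identical results either way)
    seed: int = 0


@dataclass
class SolverDiagnostics:
    dual_objective: float
    iterations: int
    max_kkt_violation: float
    slack: np.ndarray
    slack_star: np.ndarray
    converged: bool = True


@dataclass
class SVRModel:
    """Fitted dual solution plus everything needed to predict."""

    theta: np.ndarray
    alpha: np.ndarray
    alpha_star: np.ndarray
    bias: float
    support_indices: np.ndarray
    kernel: KernelSpec
    X_train: np.ndarray
    diagnostics: Optional[SolverDiagnostics] = None
    sv_tol: float = field(default=1e-8)

    def predict(self, X_new) -> np.ndarray:
        return predict(self, X_new)


def _sv_tol(C: float) -> float:
    return 1e-8 * C


def solve_dual(problem: SVRProblem, config: Optional[SolverConfig] = None) -> SVRModel:
    """Solve the epsilon-SVR dual by SMO.

    Raises
    ------
    AdmissibilityError
        If the kernel spec is inadmissible or the Gram matrix reveals
        negative curvature beyond round-off.
    ConvergenceError
        If the KKT gap does not fall below ``config.kkt_tol`` within the
        iteration budget; best-so-far diagnostics are attached.
    """
    if config is None:
        config = SolverConfig()
    if not problem.kernel.admissible:
        raise AdmissibilityError(
            f"kernel kind {problem.kernel.kind!r} is not a Mercer kernel")
    n = problem.n
    y = problem.y
    C = float(problem.C)
    eps = float(problem.epsilon)
    K = gram_matrix(problem.kernel, problem.X).values
    max_iter = config.max_iter if config.max_iter is not None else 100_000 * n

    # 2n-variable dual: beta[:n] = alpha_star (z=+1), beta[n:] = alpha (z=-1)
    z = np.concatenate([np.ones(n), -np.ones(n)])
    p = np.concatenate([eps - y, eps + y])
    beta = np.zeros(2 * n)
    G = p.copy()  # gradient of 1/2 b'Qb + p'b at beta = 0
    neg_zG = -z * G

    it = 0
    gap = np.inf
    while it < max_iter:
        up = ((z > 0) & (beta < C - 0.0)) | ((z < 0) & (beta > 0.0))
        low = ((z > 0) & (beta > 0.0)) | ((z < 0) & (beta < C - 0.0))
        cand_up = np.where(up, neg_zG, -np.inf)
        cand_low = np.where(low, neg_zG, np.inf)
        i = int(np.argmax(cand_up))
        j = int(np.argmin(cand_low))
        gap = cand_up[i] - cand_low[j]
        if not np.isfinite(gap) or gap <= config.kkt_tol:
            break
        ii, jj = i % n, j % n
        quad = K[ii, ii] + K[jj, jj] - 2.0 * K[ii, jj]
        if quad < -1e-8 * max(1.0, K[ii, ii] + K[jj, jj]):
            raise AdmissibilityError(
                "negative curvature along working pair: Gram matrix is not PSD")
        delta = gap / max(quad, 1e-12)
        # box clipping for beta_i + z_i*delta and beta_j - z_j*delta
        delta = min(delta,
                    C - beta[i] if z[i] > 0 else beta[i],
                    beta[j] if z[j] > 0 else C - beta[j])
        if delta <= 0:
            break  # numerically stuck at a boundary; gap check governs
        beta[i] += z[i] * delta
        beta[j] -= z[j] * delta
        kc = K[:, ii] - K[:, jj]
        upd = delta * np.concatenate([kc, kc])
        G += z * upd * 1.0
        neg_zG = -z * G
        it += 1

    converged = bool(gap <= config.kkt_tol)

    alpha_star = beta[:n].copy()
    alpha = beta[n:].copy()
    # canonical minimal-norm decomposition: alpha_i * alpha*_i = 0
    overlap = np.minimum(alpha, alpha_star)
    alpha -= overlap
    alpha_star -= overlap
    theta = alpha_star - alpha

    sv_tol = _sv_tol(C)
    support = np.flatnonzero(np.abs(theta) > sv_tol)
    bias = compute_bias(theta, problem, K, kkt_tol=config.kkt_tol)

    f = K @ theta + bias
    slack = np.maximum(0.0, y - f - eps)
    slack_star = np.maximum(0.0, f - y - eps)
    obj = (y @ theta) - eps * np.sum(alpha + alpha_star) - 0.5 * theta @ K @ theta
    model = SVRModel(theta=theta, alpha=alpha, alpha_star=alpha_star,
                     bias=bias, support_indices=support,
                     kernel=problem.kernel, X_train=problem.X, sv_tol=sv_tol)
    diag = SolverDiagnostics(dual_objective=float(obj), iterations=it,
                             max_kkt_violation=kkt_violation(model, problem, K=K),
                             slack=slack, slack_star=slack_star,
                             converged=converged)
    model.diagnostics = diag
    if not converged:
        raise ConvergenceError(
            f"SMO stopped after {it} iterations with KKT gap {gap:.3g} "
            f"> tol {config.kkt_tol:.3g}", diagnostics=diag)
    return model


def dual_objective(model: SVRModel, problem: SVRProblem) -> float:
    """Dual objective at the model's coefficients (larger is better)."""
    K = gram_matrix(problem.kernel, problem.X).values
    return float((problem.y @ model.theta)
                 - problem.epsilon * np.sum(model.alpha + model.alpha_star)
                 - 0.5 * model.theta @ K @ model.theta)


def compute_bias(theta: np.ndarray, problem: SVRProblem,
                 K: Optional[np.ndarray] = None,
                 kkt_tol: float = 1e-3) -> float:
    """Recover the bias b from the KKT conditions.

    Free coefficients (0 < |theta_i| < C) pin the point to a tube boundary:
    b = y_i - u_i - eps for theta_i > 0 and b = y_i - u_i + eps for
    theta_i < 0, where u = K theta; b is averaged over all free points.
    With no free point, b is the midpoint of the interval that the bound and
    interior points jointly allow.
    """
    if K is None:
        K = gram_matrix(problem.kernel, problem.X).values
    y, eps, C = problem.y, problem.epsilon, problem.C
    tol = _sv_tol(C)
    u = K @ theta
    free_up = (theta > tol) & (theta < C - tol)
    free_dn = (theta < -tol) & (theta > -C + tol)
    cands = np.concatenate([y[free_up] - u[free_up] - eps,
                            y[free_dn] - u[free_dn] + eps])
    if cands.size:
        return float(cands.mean())
    # no free SV: intersect the per-point intervals for b
    lo, hi = -np.inf, np.inf
    for i in range(problem.n):
        t = theta[i]
        r = y[i] - u[i]
        if t >= C - tol:          # at upper bound: on/above the upper tube
            hi = min(hi, r - eps)
        elif t <= -C + tol:       # at lower bound: on/below the lower tube
            lo = max(lo, r + eps)
        else:                     # interior (theta ~ 0): inside the tube
            lo = max(lo, r - eps)
            hi = min(hi, r + eps)
    if lo > hi + max(kkt_tol, 1e-9):
        raise BiasError(
            f"empty bias interval [{lo:.6g}, {hi:.6g}]; coefficients are not "
            "KKT-consistent")
    if not np.isfinite(lo):
        return float(hi) if np.isfinite(hi) else 0.0
    if not np.isfinite(hi):
        return float(lo)
    return float((lo + hi) / 2.0)


def kkt_violation(model: SVRModel, problem: SVRProblem,
                  K: Optional[np.ndarray] = None) -> float:
    """Maximum violation of the epsilon-SVR optimality conditions.

    Covers box feasibility, the equality constraint sum(theta) = 0, and
    complementarity: interior points must lie inside the tube, free support
    vectors on its boundary, and bound support vectors on or outside it.
    """
    if K is None:
        K = gram_matrix(problem.kernel, problem.X).values
    y, eps, C = problem.y, problem.epsilon, problem.C
    tol = _sv_tol(C)
    theta = model.theta
    r = y - (K @ theta) - model.bias  # signed residual y - f(x)

    viol = np.abs(np.sum(theta))                      # equality constraint
    viol = max(viol, float(np.max(np.maximum(0.0, np.abs(theta) - C), initial=0.0)))
    for i in range(problem.n):
        t = theta[i]
        if abs(t) <= tol:
            v = max(0.0, abs(r[i]) - eps)
        elif t >= C - tol:
            v = max(0.0, eps - r[i])
        elif t <= -C + tol:
            v = max(0.0, r[i] + eps)
        elif t > 0:
            v = abs(r[i] - eps)
        else:
            v = abs(r[i] + eps)
        viol = max(viol, v)
    return float(viol)


def predict(model: SVRModel, X_new) -> np.ndarray:
    """Evaluate f(x) = sum over support vectors of theta_i K(x_i, x) + b."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[:, None]
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"feature dimension {X_new.shape[1]} does not match training "
            f"dimension {model.X_train.shape[1]}")
    sv = model.support_indices
    if sv.size == 0:
        return np.full(X_new.shape[0], model.bias)
    Ksv = gram_matrix(model.kernel, model.X_train[sv], X_new).values
    return Ksv.T @ model.theta[sv] + model.bias
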