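"""Hyperparameter tuning: epsilon x C grid search, beta selection, per-group tuning.

The tuning protocol mirrors the telemonitoring study design: a small subset
of recordings is held out for tuning; candidate models are fitted and scored
on disjoint pieces of it; the selected hyperparameters are then refit on the
full training partition.  Defaults follow the study grids — epsilon in
{0, 0.1, ..., 1.0} and C in {2^2, ..., 2^9} (88 grid points) — with the
selection criterion being validation RMSE, ties broken toward smaller C and
then smaller epsilon (flatter, sparser models).  Kernel shape parameters
default to gamma = 1/d and sigma = 1 on standardized features, degree 2 for
the polynomial factor of the mixtures; all are overridable through the grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kernels import KernelSpec
from .metrics import mae, r2_paper, r2_standard, rmse
from .svr import (BiasError, ConvergenceError, SolverConfig, SVRModel,
                  SVRProblem, solve_dual)

__all__ = [
    "TuningGrid",
    "TuningResult",
    "make_kernel",
    "grid_search",
    "select_beta",
    "tune_on_subset",
    "tune_per_group",
]

DEFAULT_EPSILONS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
DEFAULT_COSTS = tuple(float(2 ** k) for k in range(2, 10))
DEFAULT_BETAS = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))


@dataclass(frozen=True)
class TuningGrid:
    """Hyperparameter grids; ``None`` for gamma or sigma means 1/d at fit
    time (the natural scale for z-scored features, where <x, x> ~ d)."""

    epsilon_values: Sequence[float] = DEFAULT_EPSILONS
    C_values: Sequence[float] = DEFAULT_COSTS
    beta_values: Sequence[float] = DEFAULT_BETAS
    gamma_values: Optional[Sequence[float]] = None
    sigma_values: Optional[Sequence[float]] = None
    p_values: Sequence[int] = (2,)

    def __post_init__(self) -> None:
        for name in ("epsilon_values", "C_values", "beta_values", "p_values"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if any(e < 0 for e in self.epsilon_values):
            raise ValueError("epsilon values must be nonnegative")
        if any(c <= 0 for c in self.C_values):
            raise ValueError("C values must be positive")
        if any(not (0 < b < 1) for b in self.beta_values):
            raise ValueError("beta values must lie in (0, 1)")


@dataclass
class TuningResult:
    best_params: dict
    score_table: pd.DataFrame
    selection_metric: str = "RMSE"
    best_model: Optional[SVRModel] = None


def make_kernel(kind: str, gamma: Optional[float] = None,
                sigma: Optional[float] = None, p: Optional[int] = None,
                beta: Optional[float] = None) -> KernelSpec:
    """Build a KernelSpec for the given kind, passing only relevant params."""
    if kind == "rbf":
        return KernelSpec(kind="rbf", gamma=gamma)
    if kind == "poly":
        return KernelSpec(kind="poly", sigma=sigma, p=p)
    if kind == "linear_raw":
        return KernelSpec(kind="linear_raw")
    if kind == "sum_mixture":
        return KernelSpec(kind="sum_mixture", gamma=gamma, sigma=sigma, p=p,
                          beta=beta)
    if kind == "product_mixture":
        return KernelSpec(kind="product_mixture", gamma=gamma, sigma=sigma,
                          p=p)
    raise ValueError(f"unknown kernel kind {kind!r}")


def _param_lists(grid: TuningGrid, kind: str, d: int, beta: Optional[float]):
    gammas = list(grid.gamma_values) if grid.gamma_values is not None \
        else [1.0 / d]
    sigmas = list(grid.sigma_values) if grid.sigma_values is not None \
        else [1.0 / d]
    ps = list(grid.p_values)
    if kind == "rbf":
        sigmas, ps = [None], [None]
    elif kind == "poly":
        gammas = [None]
    elif kind == "linear_raw":
        gammas, sigmas, ps = [None], [None], [None]
    betas = [beta] if kind == "sum_mixture" else [None]
    return gammas, sigmas, ps, betas


def grid_search(X_train: np.ndarray, y_train: np.ndarray,
                X_val: np.ndarray, y_val: np.ndarray,
                grid: TuningGrid, kernel_kind: str = "product_mixture",
                beta: Optional[float] = None,
                solver_config: Optional[SolverConfig] = None) -> TuningResult:
    """Exhaustive grid search scored on a held-out validation set.

    One model is fitted per grid point on (X_train, y_train) and scored on
    (X_val, y_val).  A fit that fails to converge is recorded with NaN scores
    and skipped by the selection; if every point fails, an error is raised.
    Selection: minimum validation RMSE, ties broken by smaller C, then
    smaller epsilon.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    d = X_train.shape[1] if X_train.ndim == 2 else 1
    if beta is None and kernel_kind == "sum_mixture":
        beta = 0.8
    gammas, sigmas, ps, betas = _param_lists(grid, kernel_kind, d, beta)
    if solver_config is None:
        solver_config = SolverConfig()

    rows = []
    for eps, C, g, s, p, b in itertools.product(
            grid.epsilon_values, grid.C_values, gammas, sigmas, ps, betas):
        kernel = make_kernel(kernel_kind, gamma=g, sigma=s, p=p, beta=b)
        row = {"epsilon": float(eps), "C": float(C), "gamma": g, "sigma": s,
               "p": p, "beta": b, "converged": True,
               "MAE": np.nan, "RMSE": np.nan, "R2_paper": np.nan,
               "R2_standard": np.nan}
        try:
            model = solve_dual(SVRProblem(X_train, y_train, C=C, epsilon=eps,
                                          kernel=kernel), solver_config)
            yhat = model.predict(X_val)
            row.update(MAE=mae(y_val, yhat), RMSE=rmse(y_val, yhat))
            try:
                row.update(R2_paper=r2_paper(y_val, yhat),
                           R2_standard=r2_standard(y_val, yhat))
            except ValueError:
                pass
        except (ConvergenceError, BiasError):
            row["converged"] = False
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["converged"] & table["RMSE"].notna()]
    if len(ok) == 0:
        raise RuntimeError("every grid point failed to converge")
    best_idx = ok.sort_values(["RMSE", "C", "epsilon"],
                              kind="stable").index[0]
    best = table.loc[best_idx]
    best_params = {"kernel": kernel_kind, "epsilon": float(best["epsilon"]),
                   "C": float(best["C"])}
    for key in ("gamma", "sigma", "p", "beta"):
        if best[key] is not None and not (isinstance(best[key], float)
                                          and np.isnan(best[key])):
            best_params[key] = best[key]
    # refit the winner on the training piece so callers can reuse it
    kernel = make_kernel(kernel_kind, gamma=best_params.get("gamma"),
                         sigma=best_params.get("sigma"),
                         p=best_params.get("p"), beta=best_params.get("beta"))
    best_model = solve_dual(SVRProblem(X_train, y_train,
                                       C=best_params["C"],
                                       epsilon=best_params["epsilon"],
                                       kernel=kernel), solver_config)
    return TuningResult(best_params=best_params, score_table=table,
                        best_model=best_model)


def select_beta(X_train, y_train, X_val, y_val, grid: TuningGrid,
                epsilon: float = 0.1, C: float = 16.0,
                gamma: Optional[float] = None, sigma: Optional[float] = None,
                p: int = 2,
                solver_config: Optional[SolverConfig] = None) -> float:
    """Choose the sum-mixture weight beta by validation RMSE.

    Fits one sum-mixture model per beta in ``grid.beta_values`` (other
    hyperparameters held fixed) and returns the argmin of validation RMSE;
    ties break toward the smaller beta.
    """
    X_train = np.asarray(X_train, dtype=float)
    d = X_train.shape[1] if X_train.ndim == 2 else 1
    if gamma is None:
        gamma = 1.0 / d
    if sigma is None:
        sigma = 1.0 / d
    if solver_config is None:
        solver_config = SolverConfig()
    best_beta, best_score = None, np.inf
    for b in grid.beta_values:
        kernel = make_kernel("sum_mixture", gamma=gamma, sigma=sigma, p=p,
                             beta=float(b))
        try:
            model = solve_dual(SVRProblem(X_train, y_train, C=C,
                                          epsilon=epsilon, kernel=kernel),
                               solver_config)
        except (ConvergenceError, BiasError):
            continue
        score = rmse(y_val, model.predict(X_val))
        if score < best_score - 1e-12:
            best_beta, best_score = float(b), score
    if best_beta is None:
        raise RuntimeError("every beta candidate failed to converge")
    return best_beta


def tune_on_subset(X_tune: np.ndarray, y_tune: np.ndarray, grid: TuningGrid,
                   kernel_kind: str = "product_mixture",
                   beta: Optional[float] = None, seed: int = 0,
                   fit_fraction: float = 2.0 / 3.0,
                   solver_config: Optional[SolverConfig] = None) -> TuningResult:
    """Grid search inside a tuning subset.

    The subset is split once (seeded) into a fit piece and a held-out
    validation piece — no cross-validation — and :func:`grid_search` is run
    across them.  The chosen hyperparameters are meant to be refit on the
    full training partition afterwards.
    """
    n = len(y_tune)
    if n < 4:
        raise ValueError("tuning subset too small to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = max(2, int(round(fit_fraction * n)))
    k = min(k, n - 1)
    fit_rows, val_rows = perm[:k], perm[k:]
    return grid_search(X_tune[fit_rows], y_tune[fit_rows],
                       X_tune[val_rows], y_tune[val_rows],
                       grid, kernel_kind=kernel_kind, beta=beta,
                       solver_config=solver_config)


def tune_per_group(dataset: pd.DataFrame, groups: np.ndarray,
                   grid: TuningGrid, kernel_kind: str = "product_mixture",
                   feature_set: str = "voice_only", target: str = "total",
                   fractions=(0.08, 0.72, 0.20), seed: int = 0,
                   solver_config: Optional[SolverConfig] = None) -> dict:
    """Independent tuning and fitting within each gender x age group.

    For every distinct group label: the group's recordings are split
    patient-proportionally, hyperparameters are tuned on the group's tuning
    subset, the winner is refit on the group's training partition, and
    train/test predictions are returned.  Groups too small to split or tune
    are skipped with a warning entry (value ``None``).

    Returns a dict group -> dict(result, model, split, scaler, y/yhat arrays).
    """
    import warnings

    from .data import feature_matrix, split_patient_proportional

    groups = np.asarray(groups)
    out: dict = {}
    for g in np.unique(groups):
        sub = dataset.loc[groups == g].reset_index(drop=True)
        if sub["subject#"].nunique() < 1 or len(sub) < 25:
            warnings.warn(f"group {g} too small to tune; skipped")
            out[int(g)] = None
            continue
        split = split_patient_proportional(sub, fractions=fractions,
                                           seed=seed + int(g))
        train_mask = split.mask("train")
        X, y, scaler = feature_matrix(sub, feature_set=feature_set,
                                      target=target, standardize=True,
                                      fit_rows=train_mask)
        tune_mask = split.mask("tune")
        if tune_mask.sum() < 8:
            # group too small for a standalone tuning subset: select
            # hyperparameters on the tune+train rows instead (the test
            # partition stays untouched either way)
            tune_mask = tune_mask | train_mask
        result = tune_on_subset(X[tune_mask], y[tune_mask], grid,
                                kernel_kind=kernel_kind, seed=seed + int(g),
                                solver_config=solver_config)
        bp = result.best_params
        kernel = make_kernel(kernel_kind, gamma=bp.get("gamma"),
                             sigma=bp.get("sigma"), p=bp.get("p"),
                             beta=bp.get("beta"))
        model = solve_dual(SVRProblem(X[train_mask], y[train_mask],
                                      C=bp["C"], epsilon=bp["epsilon"],
                                      kernel=kernel), solver_config)
        test_mask = split.mask("test")
        out[int(g)] = {
            "result": result, "model": model, "split": split,
            "scaler": scaler,
            "y_train": y[train_mask],
            "yhat_train": model.predict(X[train_mask]),
            "y_test": y[test_mask],
            "yhat_test": model.predict(X[test_mask]),
        }
    return out
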