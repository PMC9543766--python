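"""End-to-end workflows tying data, tuning, fitting and reporting together.

A run is described by a :class:`RunConfig` (parseable from a flat YAML
mapping), executed by :func:`fit_workflow` (pooled) or
:func:`grouped_workflow` (gender x age-65 groups, voice-only features), and
fully recorded — configuration, seeds and all reported numbers — in a JSON
run log so any result can be regenerated bit-for-bit.

Model persistence is a single self-describing JSON file carrying the support
vectors, dual coefficients, bias, kernel spec, scaler statistics and the
feature-column fingerprint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .data import (Scaler, assign_groups, feature_matrix,
                   split_patient_proportional)
from .kernels import KernelSpec
from .metrics import MetricsTable, gain_percentage, group_average_metrics, metrics_row
from .svr import SolverConfig, SVRModel, SVRProblem, solve_dual
from .tuning import TuningGrid, make_kernel, tune_on_subset, tune_per_group

__all__ = ["RunConfig", "fit_workflow", "grouped_workflow",
           "save_model", "load_model", "write_run_log"]


@dataclass
class RunConfig:
    """Flat, validated description of one run."""

    input_csv: Optional[str] = None     # None -> simulate
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    kernel: str = "product_mixture"
    kernel_params: dict = field(default_factory=dict)  # gamma/sigma/p/beta
    tune: bool = True
    grid: dict = field(default_factory=dict)  # TuningGrid overrides
    fractions: tuple = (0.08, 0.72, 0.20)
    seed: int = 0
    feature_set: str = "pooled"
    target: str = "total"
    grouped: bool = False
    output_dir: str = "mixsvr_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "fractions" in raw:
            raw["fractions"] = tuple(raw["fractions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(d["fractions"])
        return d

    def make_grid(self) -> TuningGrid:
        return TuningGrid(**self.grid) if self.grid else TuningGrid()

    def load_dataset(self) -> pd.DataFrame:
        if self.input_csv is not None:
            from .data import read_telemonitoring_csv
            return read_telemonitoring_csv(self.input_csv)
        from .simulate import SynthConfig, generate
        overrides = dict(self.synth)
        overrides.setdefault("seed", self.seed)
        return generate(SynthConfig(**overrides))


def fit_workflow(dataset: pd.DataFrame, config: RunConfig,
                 solver_config: Optional[SolverConfig] = None) -> dict:
    """Split, optionally tune, fit on the training partition, evaluate.

    Returns a dict with the split, scaler, fitted model, chosen
    hyperparameters and a :class:`MetricsTable` with pooled train/test rows.
    """
    if solver_config is None:
        solver_config = SolverConfig()
    split = split_patient_proportional(dataset, fractions=config.fractions,
                                       seed=config.seed)
    train_mask = split.mask("train")
    X, y, scaler = feature_matrix(dataset, feature_set=config.feature_set,
                                  target=config.target, standardize=True,
                                  fit_rows=train_mask)
    params = dict(config.kernel_params)
    if config.tune:
        tune_mask = split.mask("tune")
        result = tune_on_subset(X[tune_mask], y[tune_mask],
                                config.make_grid(),
                                kernel_kind=config.kernel,
                                beta=params.get("beta"), seed=config.seed,
                                solver_config=solver_config)
        params = dict(result.best_params)
        params.pop("kernel", None)
    else:
        result = None
        params.setdefault("epsilon", 0.1)
        params.setdefault("C", 16.0)
    d = X.shape[1]
    kernel = make_kernel(config.kernel, gamma=params.get("gamma", 1.0 / d),
                         sigma=params.get("sigma", 1.0 / d),
                         p=params.get("p", 2), beta=params.get("beta", 0.8))
    model = solve_dual(SVRProblem(X[train_mask], y[train_mask],
                                  C=params["C"], epsilon=params["epsilon"],
                                  kernel=kernel), solver_config)
    test_mask = split.mask("test")
    name = config.kernel
    rows = [metrics_row(y[train_mask], model.predict(X[train_mask]),
                        model=name, role="train"),
            metrics_row(y[test_mask], model.predict(X[test_mask]),
                        model=name, role="test")]
    return {"split": split, "scaler": scaler, "model": model,
            "params": params, "tuning": result,
            "metrics": MetricsTable.from_rows(rows)}


def grouped_workflow(dataset: pd.DataFrame, config: RunConfig,
                     reference: Optional[dict] = None,
                     solver_config: Optional[SolverConfig] = None) -> dict:
    """Per-group tuning/fitting with gains and unweighted group averages.

    Groups are gender x age-65; features are voice-only and the kernel is
    the product mixture with polynomial degree 2 unless overridden.  When a
    ``reference`` dict {"MAE": .., "RMSE": .., "R2_paper": ..} (typically the
    pooled product-mixture model's training metrics) is given, percentage
    gains per group and metric are reported against it.
    """
    if solver_config is None:
        solver_config = SolverConfig()
    groups = assign_groups(dataset)
    fits = tune_per_group(dataset, groups, config.make_grid(),
                          kernel_kind=config.kernel,
                          feature_set="voice_only", target=config.target,
                          fractions=config.fractions, seed=config.seed,
                          solver_config=solver_config)
    rows, gains = [], []
    for g, fit in sorted(fits.items()):
        if fit is None:
            continue
        for role, ykey, pkey in (("train", "y_train", "yhat_train"),
                                 ("test", "y_test", "yhat_test")):
            row = metrics_row(fit[ykey], fit[pkey], model=config.kernel,
                              role=role, group=str(g))
            rows.append(row)
            if reference is not None and role == "train":
                for metric, direction in (("MAE", "lower_is_better"),
                                          ("RMSE", "lower_is_better"),
                                          ("R2_paper", "higher_is_better")):
                    if metric in reference:
                        gains.append({
                            "group": g, "metric": metric,
                            "gain_pct": gain_percentage(reference[metric],
                                                        row[metric],
                                                        direction)})
    table = MetricsTable.from_rows(rows)
    averages = {}
    for role in ("train", "test"):
        sel = table.frame[table.frame["role"] == role]
        if len(sel):
            averages[role] = {m: group_average_metrics(sel[m].to_numpy())
                              for m in ("MAE", "RMSE", "R2_paper",
                                        "R2_standard")}
    return {"fits": fits, "metrics": table, "averages": averages,
            "gains": pd.DataFrame(gains) if gains else None}


# ---------------------------------------------------------------------------
# model persistence

def save_model(model: SVRModel, scaler: Scaler, path,
               target: str = "total") -> None:
    """Persist a fitted model (support vectors only) as self-describing JSON."""
    sv = model.support_indices
    payload = {
        "format": "mixsvr-model",
        "version": __version__,
        "kernel": model.kernel.to_dict(),
        "bias": float(model.bias),
        "theta": model.theta[sv].tolist(),
        "support_vectors": model.X_train[sv].tolist(),
        "scaler": {"mean": scaler.mean_.tolist(), "sd": scaler.sd_.tolist(),
                   "columns": list(scaler.columns)},
        "target": target,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    """Load a persisted model; returns (SVRModel, Scaler)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "mixsvr-model":
        raise ValueError(f"{path} is not a mixsvr model file")
    theta = np.asarray(payload["theta"], dtype=float)
    X_sv = np.asarray(payload["support_vectors"], dtype=float)
    if X_sv.size == 0:
        X_sv = X_sv.reshape(0, len(payload["scaler"]["columns"]))
    model = SVRModel(theta=theta, alpha=np.maximum(-theta, 0.0),
                     alpha_star=np.maximum(theta, 0.0),
                     bias=float(payload["bias"]),
                     support_indices=np.arange(theta.size),
                     kernel=KernelSpec.from_dict(payload["kernel"]),
                     X_train=X_sv)
    sc = payload["scaler"]
    scaler = Scaler(mean_=np.asarray(sc["mean"], dtype=float),
                    sd_=np.asarray(sc["sd"], dtype=float),
                    columns=tuple(sc["columns"]))
    return model, scaler


def write_run_log(path, config: RunConfig, numbers: dict) -> None:
    """Record config, seed, version and every reported number for a run."""
    log = {"version": __version__, "config": config.to_dict(),
           "numbers": numbers}
    Path(path).write_text(json.dumps(log, indent=2, default=float))
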