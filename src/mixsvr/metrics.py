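"""Regression metrics, gain percentages, group summaries and trajectories.

Two R-squared variants are reported side by side.  ``r2_paper`` is the ratio
sum((yhat_i - ybar)^2) / sum((y_i - ybar)^2) with ybar the mean of the
observed targets — a ratio of explained-to-total variation that is always
nonnegative and can exceed 1 when predictions are more dispersed than the
data.  ``r2_standard`` is the conventional 1 - RSS/TSS.  Both are computed on
every metrics row so the two can be cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "mae",
    "rmse",
    "r2_paper",
    "r2_standard",
    "gain_percentage",
    "metrics_row",
    "group_average_metrics",
    "patient_trajectory_report",
    "MetricsTable",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given inputs (e.g. constant y)."""


def _pair(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error."""
    y, yhat = _pair(y, yhat)
    return float(np.mean(np.abs(yhat - y)))


def rmse(y, yhat) -> float:
    """Root mean squared error."""
    y, yhat = _pair(y, yhat)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def r2_paper(y, yhat) -> float:
    """Explained-to-total variation ratio sum((yhat-ybar)^2)/sum((y-ybar)^2).

    Nonnegative by construction and *not* capped at 1: over-dispersed
    predictions push it above 1.  Undefined for constant ``y``.
    """
    y, yhat = _pair(y, yhat)
    ybar = y.mean()
    tss = float(np.sum((y - ybar) ** 2))
    if tss == 0.0:
        raise UndefinedMetricError("r2 is undefined for constant targets")
    return float(np.sum((yhat - ybar) ** 2) / tss)


def r2_standard(y, yhat) -> float:
    """Conventional coefficient of determination 1 - RSS/TSS."""
    y, yhat = _pair(y, yhat)
    ybar = y.mean()
    tss = float(np.sum((y - ybar) ** 2))
    if tss == 0.0:
        raise UndefinedMetricError("r2 is undefined for constant targets")
    return float(1.0 - np.sum((yhat - y) ** 2) / tss)


def gain_percentage(reference: float, value: float,
                    direction: str = "lower_is_better") -> float:
    """Percentage improvement of ``value`` over ``reference``.

    For error metrics (lower_is_better): 100*(reference - value)/reference.
    For goodness metrics (higher_is_better): 100*(value - reference)/reference.
    """
    if reference == 0:
        raise ZeroDivisionError("gain is undefined for a zero reference")
    if direction == "lower_is_better":
        return 100.0 * (reference - value) / reference
    if direction == "higher_is_better":
        return 100.0 * (value - reference) / reference
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class MetricsTable:
    """Metric rows keyed by (model, role, group); columns MAE/RMSE/R2 variants."""

    frame: pd.DataFrame

    COLUMNS = ("model", "role", "group", "MAE", "RMSE", "R2_paper", "R2_standard")

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "MetricsTable":
        frame = pd.DataFrame(list(rows), columns=list(cls.COLUMNS))
        bad = frame[frame["MAE"] > frame["RMSE"] + 1e-12]
        if len(bad):  # power-mean inequality; violation means a bug upstream
            raise ValueError("MAE > RMSE on some rows; inconsistent metrics")
        return cls(frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def metrics_row(y, yhat, model: str = "svr", role: str = "test",
                group: str = "pooled") -> dict:
    """All four metrics for one (model, role, group) cell."""
    return {
        "model": model, "role": role, "group": group,
        "MAE": mae(y, yhat), "RMSE": rmse(y, yhat),
        "R2_paper": r2_paper(y, yhat), "R2_standard": r2_standard(y, yhat),
    }


def group_average_metrics(values: Sequence[float]) -> float:
    """Unweighted arithmetic mean of one metric across groups."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no group rows to average")
    return float(values.mean())


def patient_trajectory_report(model, dataset: pd.DataFrame, split,
                              subject_id: int,
                              feature_builder) -> pd.DataFrame:
    """Time-ordered actual vs fitted/predicted UPDRS for one subject.

    Parameters
    ----------
    model
        Fitted :class:`~mixsvr.svr.SVRModel`.
    dataset
        Telemonitoring-schema frame.
    split
        :class:`~mixsvr.data.SplitAssignment` labels aligned with ``dataset``.
    subject_id
        Subject to report.
    feature_builder
        Callable mapping a sub-frame to the standardized feature matrix the
        model was trained on (typically a closure over the fitted scaler).

    Returns a frame with columns test_time, actual, predicted, split ordered
    by test_time; training rows carry in-sample fitted values, test rows
    out-of-sample predictions.
    """
    mask = dataset["subject#"].to_numpy() == subject_id
    if not mask.any():
        raise KeyError(f"unknown subject {subject_id}")
    sub = dataset.loc[mask]
    labels = np.asarray(split.labels)[mask]
    X = feature_builder(sub)
    out = pd.DataFrame({
        "test_time": sub["test_time"].to_numpy(),
        "actual": sub["total_UPDRS"].to_numpy(),
        "predicted": model.predict(X),
        "split": labels,
    })
    return out.sort_values("test_time", kind="stable").reset_index(drop=True)
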