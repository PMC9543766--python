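"""Telemonitoring table I/O, descriptive statistics, splits and grouping.

The canonical schema is the UCI Parkinson's Telemonitoring table: one row per
voice recording with subject identity, demographics (age in years, sex coded
0 = male / 1 = female), test_time in days since recruitment, the two UPDRS
targets, and 16 acoustic voice measures (jitter and shimmer families, noise
ratios NHR/HNR, and the nonlinear measures RPDE, DFA, PPE).

Because recordings repeat within subjects, train/test splits must preserve
subjects' proportions: each patient contributes (approximately) the same
fraction of their recordings to each of the tune/train/test partitions, via
largest-remainder rounding within patient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "VOICE_FEATURES",
    "SchemaError",
    "Scaler",
    "SplitAssignment",
    "read_telemonitoring_csv",
    "validate_schema",
    "describe",
    "split_patient_proportional",
    "assign_groups",
    "feature_matrix",
]

VOICE_FEATURES = (
    "Jitter(%)", "Jitter(Abs)", "Jitter:RAP", "Jitter:PPQ5", "Jitter:DDP",
    "Shimmer", "Shimmer(dB)", "Shimmer:APQ3", "Shimmer:APQ5", "Shimmer:APQ11",
    "Shimmer:DDA", "NHR", "HNR", "RPDE", "DFA", "PPE",
)

COLUMNS = ("subject#", "age", "sex", "test_time", "motor_UPDRS",
           "total_UPDRS") + VOICE_FEATURES

JITTER_BLOCK = VOICE_FEATURES[0:5]
SHIMMER_BLOCK = VOICE_FEATURES[5:11]


class SchemaError(ValueError):
    """The table does not match the canonical telemonitoring schema."""


def validate_schema(frame: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing/renamed columns: {missing}")
    if len(frame) == 0:
        raise SchemaError("table has no rows")
    for col in COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise SchemaError(
                f"non-numeric or non-finite value in column {col!r} at row "
                f"{int(bad[0])}")


def read_telemonitoring_csv(path) -> pd.DataFrame:
    """Read and validate a telemonitoring CSV; row order is preserved."""
    frame = pd.read_csv(path)
    validate_schema(frame)
    frame = frame[list(COLUMNS)].copy()
    for col in COLUMNS:
        frame[col] = pd.to_numeric(frame[col])
    frame["subject#"] = frame["subject#"].astype(int)
    return frame


def describe(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-feature mean / median / sample SD (sex excluded)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    cols = [c for c in COLUMNS if c not in ("subject#", "sex")]
    rows = []
    for col in cols:
        v = dataset[col].to_numpy(dtype=float)
        rows.append({"feature": col, "mean": float(v.mean()),
                     "median": float(np.median(v)),
                     "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0})
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class SplitAssignment:
    """Per-recording tune/train/test labels with the fractions and seed used."""

    labels: np.ndarray           # array of {"tune","train","test"}
    fractions: tuple
    seed: int

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def counts(self) -> dict:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


# label priority when a patient has fewer recordings than labels, and for
# breaking remainder ties: train first, then test, then tune
_LABELS = ("tune", "train", "test")
_PRIORITY = {"train": 0, "test": 1, "tune": 2}


def _largest_remainder(m: int, fractions: Sequence[float]) -> dict:
    exact = np.asarray(fractions, dtype=float) * m
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = m - int(base.sum())
    order = sorted(range(len(_LABELS)),
                   key=lambda k: (-rem[k], _PRIORITY[_LABELS[k]]))
    counts = dict(zip(_LABELS, base.tolist()))
    for k in order[:short]:
        counts[_LABELS[k]] += 1
    return counts


def split_patient_proportional(dataset: pd.DataFrame,
                               fractions=(0.08, 0.72, 0.20),
                               seed: int = 0,
                               tune_mode: str = "proportional") -> SplitAssignment:
    """Assign each recording to tune/train/test, patient-proportionally.

    ``fractions`` are (tune, train, test) and must sum to 1.  Within each
    patient the label counts follow largest-remainder rounding of the
    fractions and the recordings are permuted with the given seed.  With
    ``tune_mode="uniform"`` the tune subset is instead drawn uniformly over
    all recordings and the remaining rows are split patient-proportionally
    between train and test.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("need three nonnegative fractions (tune, train, test)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {sum(fractions)}, expected 1")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    labels = np.empty(n, dtype=object)
    subjects = dataset["subject#"].to_numpy()

    if tune_mode == "uniform":
        n_tune = int(round(fractions[0] * n))
        tune_rows = rng.choice(n, size=n_tune, replace=False)
        rest = np.setdiff1d(np.arange(n), tune_rows)
        labels[tune_rows] = "tune"
        rest_total = fractions[1] + fractions[2]
        for sid in np.unique(subjects):
            rows = rest[subjects[rest] == sid]
            counts = _largest_remainder(
                rows.size, (0.0, fractions[1] / rest_total,
                            fractions[2] / rest_total))
            perm = rng.permutation(rows)
            k = counts["train"]
            labels[perm[:k]] = "train"
            labels[perm[k:]] = "test"
    elif tune_mode == "proportional":
        for sid in np.unique(subjects):
            rows = np.flatnonzero(subjects == sid)
            counts = _largest_remainder(rows.size, fractions)
            perm = rng.permutation(rows)
            a = counts["tune"]
            b = a + counts["train"]
            labels[perm[:a]] = "tune"
            labels[perm[a:b]] = "train"
            labels[perm[b:]] = "test"
    else:
        raise ValueError(f"unknown tune_mode {tune_mode!r}")
    return SplitAssignment(labels=labels.astype(str), fractions=fractions,
                           seed=seed)


def assign_groups(dataset: pd.DataFrame, age_threshold: float = 65.0) -> np.ndarray:
    """Gender x age group labels: 1 = women under the threshold, 2 = men
    under, 3 = women at/above, 4 = men at/above.

    Age exactly equal to the threshold goes to the older group.
    """
    age = dataset["age"].to_numpy(dtype=float)
    sex = dataset["sex"].to_numpy(dtype=int)  # 0 = male, 1 = female
    older = age >= age_threshold
    female = sex == 1
    groups = np.where(~older & female, 1,
                      np.where(~older & ~female, 2,
                               np.where(older & female, 3, 4)))
    return groups.astype(int)


@dataclass
class Scaler:
    """Column-wise z-score scaler with frozen training statistics."""

    mean_: np.ndarray
    sd_: np.ndarray
    columns: tuple

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.sd_ + self.mean_


def _identity_scaler(cols) -> Scaler:
    k = len(cols)
    return Scaler(mean_=np.zeros(k), sd_=np.ones(k), columns=tuple(cols))


def feature_matrix(dataset: pd.DataFrame, feature_set: str = "pooled",
                   target: str = "total", standardize: bool = True,
                   fit_rows: Optional[np.ndarray] = None,
                   custom_columns: Optional[Sequence[str]] = None):
    """Assemble (X, y, scaler) from a telemonitoring frame.

    feature_set ``pooled`` = 16 voice measures + age + sex; ``voice_only`` =
    the 16 voice measures; ``custom`` uses ``custom_columns``.  The z-score
    scaler is fitted on ``fit_rows`` only (a boolean mask; default: all rows)
    and applied to every row, so held-out rows never leak into the scaling.
    Constant columns keep SD 1 to stay invertible.
    """
    if feature_set == "pooled":
        cols = list(VOICE_FEATURES) + ["age", "sex"]
    elif feature_set == "voice_only":
        cols = list(VOICE_FEATURES)
    elif feature_set == "custom":
        if not custom_columns:
            raise ValueError("custom feature_set requires custom_columns")
        cols = list(custom_columns)
    else:
        raise ValueError(f"unknown feature_set {feature_set!r}")
    unknown = [c for c in cols if c not in dataset.columns]
    if unknown:
        raise ValueError(f"unknown feature columns: {unknown}")
    target_col = {"total": "total_UPDRS", "motor": "motor_UPDRS"}.get(target)
    if target_col is None:
        raise ValueError(f"unknown target {target!r}")

    X = dataset[cols].to_numpy(dtype=float)
    y = dataset[target_col].to_numpy(dtype=float)
    if not standardize:
        return X, y, _identity_scaler(cols)
    rows = X if fit_rows is None else X[np.asarray(fit_rows)]
    if rows.shape[0] == 0:
        raise ValueError("fit_rows selects no rows for the scaler")
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    scaler = Scaler(mean_=mean, sd_=sd, columns=tuple(cols))
    return scaler.transform(X), y, scaler
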