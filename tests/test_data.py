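"""Telemonitoring I/O, descriptive statistics, splits and grouping."""

import numpy as np
import pandas as pd
import pytest

from mixsvr.data import (COLUMNS, VOICE_FEATURES, SchemaError, assign_groups,
                         describe, feature_matrix, read_telemonitoring_csv,
                         split_patient_proportional)
from mixsvr.simulate import SynthConfig, generate, write_csv


def test_reader_round_trips_generated_files(tmp_path, small_cohort):
    path = tmp_path / "synth.csv"
    write_csv(small_cohort, path)
    back = read_telemonitoring_csv(path)
    assert list(back.columns) == list(COLUMNS)
    assert len(back) == len(small_cohort)
    pd.testing.assert_frame_equal(back, small_cohort[list(COLUMNS)],
                                  check_exact=False, rtol=0, atol=1e-12)


def test_three_row_file_round_trips(tmp_path):
    ds = generate(SynthConfig(n_patients=1, mean_recordings_per_patient=3,
                              seed=5)).head(3)
    path = tmp_path / "three.csv"
    write_csv(ds, path)
    assert len(read_telemonitoring_csv(path)) == 3


def test_renamed_column_gives_schema_error_naming_it(tmp_path, small_cohort):
    bad = small_cohort.rename(columns={"HNR": "hnr"})
    path = tmp_path / "bad.csv"
    bad.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="HNR"):
        read_telemonitoring_csv(path)


def test_non_numeric_cell_reports_row(tmp_path, small_cohort):
    frame = small_cohort.head(4).copy().astype(object)
    frame.loc[2, "PPE"] = "oops"
    path = tmp_path / "nan.csv"
    frame.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="PPE"):
        read_telemonitoring_csv(path)


def test_header_only_file_errors_informatively(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text(",".join(COLUMNS) + "\n")
    with pytest.raises(SchemaError, match="no rows"):
        read_telemonitoring_csv(path)


def test_describe_matches_hand_arithmetic():
    rows = []
    for i, (tt, updrs, hnr) in enumerate([(0.0, 10.0, 20.0),
                                          (10.0, 20.0, 22.0),
                                          (20.0, 36.0, 24.0)]):
        row = {c: 0.5 for c in COLUMNS}
        row.update({"subject#": 1, "age": 60 + i, "sex": 0, "test_time": tt,
                    "motor_UPDRS": updrs - 5, "total_UPDRS": updrs,
                    "HNR": hnr})
        rows.append(row)
    table = describe(pd.DataFrame(rows))
    assert table.loc["total_UPDRS", "mean"] == pytest.approx(22.0)
    assert table.loc["total_UPDRS", "median"] == pytest.approx(20.0)
    assert table.loc["total_UPDRS", "sd"] == pytest.approx(
        np.std([10, 20, 36], ddof=1))
    assert table.loc["HNR", "sd"] == pytest.approx(2.0)
    assert table.loc["PPE", "sd"] == 0.0          # constant column
    assert "sex" not in table.index


def test_split_partitions_with_patient_proportions(small_cohort):
    split = split_patient_proportional(small_cohort, seed=3)
    counts = split.counts()
    assert sum(counts.values()) == len(small_cohort)
    subjects = small_cohort["subject#"].to_numpy()
    for sid in np.unique(subjects):
        m = subjects == sid
        n = int(m.sum())
        n_train = int((split.labels[m] == "train").sum())
        assert abs(n_train / n - 0.72) <= 1.0 / n + 1e-9


def test_largest_remainder_example():
    frame = pd.DataFrame({c: 0.1 for c in COLUMNS}, index=range(10))
    frame["subject#"] = 1
    split = split_patient_proportional(frame, fractions=(0.1, 0.7, 0.2),
                                       seed=0)
    assert split.counts() == {"tune": 1, "train": 7, "test": 2}


def test_single_recording_patient_goes_to_train():
    frame = pd.DataFrame([{c: 0.1 for c in COLUMNS}])
    frame["subject#"] = 9
    split = split_patient_proportional(frame, seed=0)
    assert list(split.labels) == ["train"]


def test_split_seed_reproducibility(small_cohort):
    a = split_patient_proportional(small_cohort, seed=11)
    b = split_patient_proportional(small_cohort, seed=11)
    c = split_patient_proportional(small_cohort, seed=12)
    assert np.array_equal(a.labels, b.labels)
    assert not np.array_equal(a.labels, c.labels)
    assert a.counts() == c.counts()


def test_uniform_tune_mode_partitions(small_cohort):
    split = split_patient_proportional(small_cohort, seed=2,
                                       tune_mode="uniform")
    counts = split.counts()
    assert sum(counts.values()) == len(small_cohort)
    assert counts["tune"] == round(0.08 * len(small_cohort))


def test_bad_fractions_rejected(small_cohort):
    with pytest.raises(ValueError):
        split_patient_proportional(small_cohort, fractions=(0.5, 0.4, 0.2))


def test_group_assignment_boundaries():
    frame = pd.DataFrame({"age": [60, 70, 60, 70, 65],
                          "sex": [1, 0, 0, 1, 0]})
    assert list(assign_groups(frame)) == [1, 4, 2, 3, 4]


def test_groups_constant_within_patient(small_cohort):
    groups = assign_groups(small_cohort)
    frame = small_cohort.assign(group=groups)
    assert (frame.groupby("subject#")["group"].nunique() == 1).all()


def test_feature_matrix_sets_and_scaling(small_cohort):
    X, y, scaler = feature_matrix(small_cohort, "voice_only", "total")
    assert X.shape[1] == 16
    Xp, _, _ = feature_matrix(small_cohort, "pooled", "total")
    assert Xp.shape[1] == 18
    assert np.allclose(X.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(X.std(axis=0), 1.0, atol=1e-9)
    # scaler round-trip
    back = scaler.transform(scaler.inverse_transform(X))
    assert np.allclose(back, X, atol=1e-10)


def test_scaler_fits_on_training_rows_only(small_cohort):
    mask = np.zeros(len(small_cohort), dtype=bool)
    mask[: len(small_cohort) // 2] = True
    X, _, _ = feature_matrix(small_cohort, "voice_only", "total",
                             fit_rows=mask)
    assert np.allclose(X[mask].mean(axis=0), 0.0, atol=1e-9)
    assert not np.allclose(X[~mask].mean(axis=0), 0.0, atol=1e-3)


def test_custom_features_and_errors(small_cohort):
    X, y, _ = feature_matrix(small_cohort, "custom", "motor",
                             custom_columns=["HNR", "PPE", "test_time"])
    assert X.shape[1] == 3
    assert np.allclose(y, small_cohort["motor_UPDRS"])
    with pytest.raises(ValueError, match="unknown feature"):
        feature_matrix(small_cohort, "custom", "total",
                       custom_columns=["nope"])
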