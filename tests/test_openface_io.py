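import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facedep import schema, synthetic
from facedep.openface_io import (
    DEFAULT_HORIZON,
    FeatureScaler,
    RawFeatureTable,
    SchemaError,
    join_participant_segments,
    load_cohort,
    pad_to_horizon,
    read_manifest,
    read_openface_csv,
    save_cohort,
    select_features,
)


def write_csv(tmp_path, table, name="seg.csv", mutate=None):
    df = table.to_frame()
    if mutate is not None:
        df = mutate(df)
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


def make_table(n_rows, seed=0):
    spec = synthetic.SignatureSpec(duration_s=n_rows / 30.0)
    return synthetic.generate_participant("mild", spec, seed=seed)


class TestReadCsv:
    def test_identity_parse(self, tmp_path):
        table = make_table(10)
        parsed = read_openface_csv(write_csv(tmp_path, table))
        assert len(parsed) == 10
        assert parsed.values.shape == (10, 49)
        np.testing.assert_array_equal(parsed.values, table.values)

    def test_extra_columns_dropped(self, tmp_path):
        table = make_table(5)
        path = write_csv(
            tmp_path, table,
            mutate=lambda df: df.assign(confidence=0.99, success=1),
        )
        parsed = read_openface_csv(path)
        assert parsed.values.shape == (5, 49)
        assert parsed.columns == list(schema.ALL_FEATURES)

    def test_missing_column_named_in_error(self, tmp_path):
        table = make_table(5)
        path = write_csv(
            tmp_path, table, mutate=lambda df: df.drop(columns=["gaze_angle_x"])
        )
        with pytest.raises(SchemaError, match="gaze_angle_x"):
            read_openface_csv(path)

    def test_openface_spacey_headers(self, tmp_path):
        # raw OpenFace output pads every header cell with a leading space
        table = make_table(5)
        path = write_csv(
            tmp_path, table,
            mutate=lambda df: df.rename(columns={c: f" {c}" for c in df.columns}),
        )
        parsed = read_openface_csv(path)
        np.testing.assert_array_equal(parsed.values, table.values)

    def test_non_increasing_frames_rejected(self):
        with pytest.raises(SchemaError, match="strictly increasing"):
            RawFeatureTable(
                frame_index=np.array([0, 2, 1]),
                timestamp=np.zeros(3),
                values=np.zeros((3, 49)),
            )


class TestJoin:
    def test_length_additivity(self):
        joined = join_participant_segments([make_table(5), make_table(7, seed=1)])
        assert len(joined) == 12

    def test_single_table_renumbered(self):
        table = make_table(6)
        joined = join_participant_segments([table])
        np.testing.assert_array_equal(joined.values, table.values)
        np.testing.assert_array_equal(joined.frame_index, np.arange(6))

    def test_three_segments_concatenate_in_order(self):
        tables = [make_table(10, seed=s) for s in range(3)]
        joined = join_participant_segments(tables)
        # brute-force oracle: plain row-stacking in list order
        expected = np.concatenate([t.values for t in tables], axis=0)
        assert len(joined) == 30
        np.testing.assert_array_equal(joined.values, expected)
        np.testing.assert_array_equal(joined.frame_index, np.arange(30))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            join_participant_segments([])

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=12), min_size=1,
                    max_size=5))
    def test_join_length_is_sum_of_segments(self, lengths):
        tables = [
            RawFeatureTable(np.arange(n), np.arange(n) / 30.0,
                            np.random.default_rng(n).random((n, 49)))
            for n in lengths
        ]
        assert len(join_participant_segments(tables)) == sum(lengths)


class TestSelectFeatures:
    def test_forty_columns(self, tiny_table):
        series = select_features(tiny_table)
        assert series.values.shape[1] == 40

    def test_group_widths(self, tiny_table):
        series = select_features(tiny_table)
        widths = {k: sl.stop - sl.start for k, sl in series.group_slices.items()}
        assert widths == {"Pose": 3, "Gaze": 2, "AU_r": 17, "AU_c": 18}

    def test_dropped_columns_absent(self, tiny_table):
        series = select_features(tiny_table)
        for dropped in schema.POSE_LOCATION + schema.GAZE_VECTOR:
            assert dropped not in series.feature_names

    def test_retained_values_match_source(self, tiny_table):
        series = select_features(tiny_table)
        for j, name in enumerate(series.feature_names):
            np.testing.assert_array_equal(series.values[:, j],
                                          tiny_table.column(name))

    def test_idempotent_on_selected_series(self, tiny_table):
        series = select_features(tiny_table)
        assert select_features(series) is series


class TestPadding:
    def test_default_horizon_is_eleven_minutes(self):
        assert DEFAULT_HORIZON == 19_800

    def test_exact_length_unchanged(self, tiny_table):
        series = select_features(tiny_table)
        padded = pad_to_horizon(series, horizon=len(series))
        np.testing.assert_array_equal(padded.values, series.values)

    def test_pad_appends_zero_rows(self):
        series = select_features(make_table(100))
        padded = pad_to_horizon(series, horizon=300)
        assert len(padded) == 300
        assert padded.original_length == 100
        # the nonzero-row boundary sits exactly at the original length
        row_nonzero = np.any(padded.values != 0, axis=1)
        assert not row_nonzero[100:].any()
        np.testing.assert_array_equal(padded.values[:100], series.values)

    def test_too_long_rejected(self):
        series = select_features(make_table(60))
        with pytest.raises(ValueError, match="exceeds"):
            pad_to_horizon(series, horizon=59)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(min_value=1, max_value=40),
           st.integers(min_value=0, max_value=50))
    def test_padding_preserves_prefix_bit_exactly(self, n_rows, extra):
        series = select_features(make_table(n_rows, seed=n_rows))
        padded = pad_to_horizon(series, horizon=n_rows + extra)
        np.testing.assert_array_equal(padded.values[:n_rows], series.values)


class TestScaler:
    def test_train_stats_standardize(self):
        series = [select_features(make_table(120, seed=s)) for s in range(3)]
        scaler = FeatureScaler().fit(series)
        stacked = np.concatenate(
            [scaler.transform(s).values for s in series], axis=0)
        np.testing.assert_allclose(stacked.mean(axis=0), 0.0, atol=1e-9)

    def test_padding_stays_zero_after_scaling(self):
        series = select_features(make_table(50))
        scaler = FeatureScaler().fit([series])
        padded = pad_to_horizon(scaler.transform(series), horizon=80)
        assert np.all(padded.values[50:] == 0.0)

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            FeatureScaler().transform(select_features(make_table(5)))


def test_cohort_archive_round_trip(tmp_path):
    series = [select_features(make_table(30, seed=s), f"P{s}") for s in range(3)]
    series = [pad_to_horizon(s, 60) for s in series]
    path = tmp_path / "cohort.npz"
    save_cohort(path, series, ["mild", "normal", "severe"])
    loaded, severities, scaler = load_cohort(path)
    assert severities == ["mild", "normal", "severe"]
    assert scaler is None
    for a, b in zip(series, loaded):
        assert a.participant_id == b.participant_id
        assert a.original_length == b.original_length
        np.testing.assert_array_equal(a.values, b.values)


def test_manifest_requires_columns(tmp_path):
    path = tmp_path / "manifest.csv"
    pd.DataFrame({"participant_id": ["a"], "file_path": ["x.csv"]}).to_csv(
        path, index=False)
    with pytest.raises(SchemaError, match="severity"):
        read_manifest(path)
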