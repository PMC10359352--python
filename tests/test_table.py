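"""Feature-table I/O, min-max scaling and the train/validation/test split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fermgan.table import (
    FEATURE_COLUMNS,
    ConfigError,
    DegenerateFeatureError,
    FeatureTable,
    ParseError,
    ScalerParams,
    SchemaError,
    SplitSpec,
    apply_scaler,
    fit_scaler,
    invert_scaler,
    load_table,
    split_data,
    split_sizes,
)


def _table(values, labels=None):
    values = np.asarray(values, float)
    if labels is None:
        labels = np.ones(len(values), int)
    return FeatureTable(values, labels)


class TestLoadTable:
    def test_round_trip_preserves_rows_and_labels(self, design20, tmp_path):
        path = tmp_path / "design.csv"
        design20.to_csv(path)
        loaded = load_table(path)
        assert len(loaded) == 20
        np.testing.assert_allclose(loaded.values, design20.values)
        np.testing.assert_array_equal(loaded.labels, design20.labels)

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"time": [1, 2], "temperature": [3, 4], "dose": [0, 1]}).to_csv(
            path, index=False
        )
        with pytest.raises(SchemaError, match="alcohol"):
            load_table(path)

    def test_non_numeric_cell_cites_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        df = pd.DataFrame(
            {"time": [1, 2, 3, 4], "temperature": [30] * 4, "dose": [1] * 4, "alcohol": [1, 2, "abc", 4]}
        )
        df.to_csv(path, index=False)
        with pytest.raises(ParseError, match="row 2"):
            load_table(path)

    def test_invalid_labels_rejected(self):
        with pytest.raises(SchemaError):
            FeatureTable(np.ones((2, 4)), np.array([1, 7]))


class TestScaler:
    def test_affine_map_hits_target_endpoints(self):
        t = _table(np.column_stack([[0, 36, 72], [25, 35, 45], [0, 1, 2], [1, 5, 9]]))
        params = fit_scaler(t, (-1.0, 1.0))
        scaled = apply_scaler(t, params)
        np.testing.assert_allclose(scaled.values[:, 0], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(scaled.values.min(axis=0), -1.0)
        np.testing.assert_allclose(scaled.values.max(axis=0), 1.0)

    def test_unit_range(self):
        t = _table([[2, 2, 2, 2], [4, 4, 4, 4]])
        scaled = apply_scaler(t, fit_scaler(t, (0.0, 1.0)))
        np.testing.assert_allclose(scaled.values, [[0, 0, 0, 0], [1, 1, 1, 1]])

    def test_midpoint_inverts_to_feature_mean(self):
        params = ScalerParams(np.array([10.0] * 4), np.array([30.0] * 4), (-1.0, 1.0))
        np.testing.assert_allclose(params.inverse_transform(np.zeros((1, 4))), 20.0)

    def test_degenerate_feature_named(self):
        t = _table([[5, 1, 0, 1], [5, 2, 1, 2]])
        with pytest.raises(DegenerateFeatureError, match="time"):
            fit_scaler(t)

    def test_matches_reference_minmax_implementation(self, design20):
        from sklearn.preprocessing import MinMaxScaler

        params = fit_scaler(design20, (-1.0, 1.0))
        ref = MinMaxScaler(feature_range=(-1, 1)).fit_transform(design20.values)
        np.testing.assert_allclose(apply_scaler(design20, params).values, ref, atol=1e-12)

    def test_json_round_trip(self, design20, tmp_path):
        params = fit_scaler(design20)
        path = tmp_path / "scaler.json"
        params.to_json(path)
        loaded = ScalerParams.from_json(path)
        np.testing.assert_allclose(loaded.feature_mins, params.feature_mins)
        np.testing.assert_allclose(loaded.feature_maxs, params.feature_maxs)
        assert loaded.feature_range == params.feature_range

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_identity_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(-50, 50, size=(rng.integers(2, 30), 4))
        values += rng.uniform(0.1, 1.0, 4)  # avoid accidentally constant columns
        values[0] -= 1.0
        t = _table(values)
        params = fit_scaler(t)
        back = invert_scaler(apply_scaler(t, params), params)
        np.testing.assert_allclose(back.values, t.values, rtol=1e-12, atol=1e-12)

    def test_schema_mismatch_rejected(self, design20):
        params = ScalerParams(np.zeros(4), np.ones(4), (-1, 1), ("a", "b", "c", "d"))
        with pytest.raises(SchemaError):
            apply_scaler(design20, params)


class TestSplit:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (220, (127, 84, 9)),  # largest-remainder seats: test, then validation
            (100, (58, 38, 4)),  # exact fractions
            (20, (11, 8, 1)),
            (3, (1, 1, 1)),
        ],
    )
    def test_largest_remainder_sizes(self, n, expected):
        assert split_sizes(n, (0.58, 0.38, 0.04)) == expected

    def test_partition_is_disjoint_and_exhaustive(self, design20):
        tr, va, te = split_data(design20, SplitSpec(seed=5))
        combined = np.vstack([tr.values, va.values, te.values])
        assert combined.shape == design20.values.shape
        # multiset equality via lexicographic sort
        np.testing.assert_allclose(
            np.sort(combined, axis=0), np.sort(design20.values, axis=0)
        )
        assert len(tr) + len(va) + len(te) == len(design20)
        assert len(te) >= 1

    def test_same_seed_same_membership(self, design20):
        a = split_data(design20, SplitSpec(seed=9))
        b = split_data(design20, SplitSpec(seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigError):
            SplitSpec((0.5, 0.4, 0.2))


def test_welch_statistic_invariant_to_common_affine_rescale():
    """Pre-test min-max normalisation cannot change the Welch t statistic."""
    from fermgan.fidelity import welch_test

    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 14), rng.normal(0.4, 2, 9)
    t0 = welch_test(a, b).statistic
    t1 = welch_test(5.0 * a - 7.0, 5.0 * b - 7.0).statistic
    assert t0 == pytest.approx(t1, abs=1e-9)
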