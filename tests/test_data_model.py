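import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miskit.data_model import (
    DataMatrix,
    extract_patterns,
    missing_summary,
    pattern_correlation,
    read_csv,
    write_csv,
)
from miskit.exceptions import ParseError, ValidationError

from conftest import make_matrix


def _write(tmp_path, text, name="data.csv"):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestReadCsv:
    def test_empty_cell_becomes_missing(self, tmp_path):
        path = _write(tmp_path, "a,b\n1,2\n3,\n5,6\n")
        dm = read_csv(path)
        assert dm.values.shape == (3, 2)
        assert dm.mask.sum() == 1
        assert dm.mask[1, 1]

    def test_custom_missing_token(self, tmp_path):
        path = _write(tmp_path, "a,b\n1,NA\n3,4\n")
        dm = read_csv(path, missing_tokens={"", "NA"})
        assert dm.mask[0, 1] and dm.mask.sum() == 1

    def test_outcome_column_split(self, tmp_path):
        path = _write(tmp_path, "a,b,Y\n1,2,0\n3,4,1\n5,6,0\n")
        dm = read_csv(path, outcome_col="Y")
        assert dm.p == 2
        assert dm.outcome is not None and dm.outcome.shape == (3,)
        np.testing.assert_array_equal(dm.outcome, [0, 1, 0])

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = _write(tmp_path, "a,b\n1,2\n3,oops\n")
        with pytest.raises(ParseError, match="row 2.*'b'"):
            read_csv(path)

    def test_duplicate_columns_rejected(self, tmp_path):
        path = _write(tmp_path, "a,a\n1,2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_csv(path)

    def test_missing_outcome_rejected(self, tmp_path):
        path = _write(tmp_path, "a,Y\n1,\n2,1\n")
        with pytest.raises(ParseError, match="outcome"):
            read_csv(path, outcome_col="Y")


@settings(max_examples=25, deadline=None)
@given(
    st.lists(
        st.lists(
            st.one_of(
                st.floats(allow_nan=False, allow_infinity=False, width=64),
                st.none(),
            ),
            min_size=3,
            max_size=3,
        ),
        min_size=1,
        max_size=8,
    )
)
def test_csv_round_trip_is_lossless(tmp_path_factory, rows):
    """Writing then reading reproduces values, mask and names exactly."""
    vals = np.array(
        [[np.nan if c is None else c for c in row] for row in rows], dtype=float
    )
    dm = make_matrix(vals)
    path = tmp_path_factory.mktemp("rt") / "m.csv"
    write_csv(dm, path)
    back = read_csv(path, id_col="sample_id")
    np.testing.assert_array_equal(back.mask, dm.mask)
    np.testing.assert_array_equal(
        back.values[~back.mask], dm.values[~dm.mask]
    )
    assert back.feature_names == dm.feature_names


class TestMissingSummary:
    def test_total_percentage(self):
        vals = np.arange(20, dtype=float).reshape(4, 5)
        vals[0, 0] = np.nan
        vals[3, 2] = np.nan
        s = missing_summary(make_matrix(vals))
        assert s.total_pct == pytest.approx(10.0)

    def test_fully_observed_single_pattern(self):
        s = missing_summary(make_matrix(np.ones((6, 3))))
        assert len(s.pattern_table) == 1
        q = s.pattern_table[0]
        assert all(q.signature) and q.count == 6

    def test_per_feature_percentage(self):
        vals = np.ones((10, 5))
        vals[:3, 0] = np.nan
        s = missing_summary(make_matrix(vals))
        assert s.per_feature_pct[0] == pytest.approx(30.0)
        assert s.per_feature_pct[1] == pytest.approx(0.0)

    def test_total_equals_mean_of_feature_percentages(self, rng):
        vals = rng.normal(size=(30, 4))
        vals[rng.random(vals.shape) < 0.25] = np.nan
        s = missing_summary(make_matrix(vals))
        assert s.total_pct == pytest.approx(s.per_feature_pct.mean())


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10**9))
def test_patterns_partition_rows(seed):
    r = np.random.default_rng(seed)
    mask = r.random((r.integers(1, 20), r.integers(1, 6))) < 0.4
    patterns = extract_patterns(mask)
    rows = sorted(i for q in patterns for i in q.row_indices)
    assert rows == list(range(mask.shape[0]))
    counts = [q.count for q in patterns]
    assert counts == sorted(counts, reverse=True)
    for q in patterns:
        assert q.count >= 1
        assert list(q.observed_idx) == [
            j for j, s in enumerate(q.signature) if s
        ]


class TestPatternCorrelation:
    def test_identical_indicators(self):
        vals = np.ones((6, 2))
        vals[[0, 3], 0] = np.nan
        vals[[0, 3], 1] = np.nan
        corr = pattern_correlation(make_matrix(vals))
        assert corr[0, 1] == pytest.approx(1.0)

    def test_complementary_indicators(self):
        vals = np.ones((6, 2))
        vals[:3, 0] = np.nan
        vals[3:, 1] = np.nan
        corr = pattern_correlation(make_matrix(vals))
        assert corr[0, 1] == pytest.approx(-1.0)

    def test_independent_indicators_near_zero(self):
        r = np.random.default_rng(7)
        vals = np.ones((10000, 2))
        vals[r.random(10000) < 0.3, 0] = np.nan
        vals[r.random(10000) < 0.3, 1] = np.nan
        corr = pattern_correlation(make_matrix(vals))
        assert abs(corr[0, 1]) < 0.05

    def test_constant_indicator_marked_undefined(self):
        vals = np.ones((5, 3))
        vals[2, 1] = np.nan
        corr = pattern_correlation(make_matrix(vals))
        assert np.isnan(corr[0, :]).all()  # fully observed feature
        assert corr[1, 1] == pytest.approx(1.0)


class TestDataMatrixInvariants:
    def test_outcome_length_checked(self):
        with pytest.raises(ValidationError):
            DataMatrix(np.ones((3, 2)), ["a", "b"], outcome=np.array([1.0, 2.0]))

    def test_outcome_missing_rejected(self):
        with pytest.raises(ValidationError):
            DataMatrix(
                np.ones((2, 2)), ["a", "b"], outcome=np.array([1.0, np.nan])
            )

    def test_all_missing_features_flagged_not_dropped(self):
        vals = np.ones((4, 2))
        vals[:, 1] = np.nan
        dm = make_matrix(vals, names=["a", "b"])
        assert dm.p == 2
        assert dm.all_missing_features() == ["b"]
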