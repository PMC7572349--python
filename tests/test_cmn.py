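import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmnet.atlas import ROIParcellation
from cmnet.cmn import (
    CMNValidationError,
    CorticalAttributeTable,
    EdgeIndexMap,
    average_roi_measurement,
    build_cmn,
    build_feature_table,
    devectorize_cmn,
    read_aparc_stats,
    read_tidy_csv,
    tables_to_tidy_frame,
    vectorize_cmn,
)

finite_means = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2, max_size=12
)


def random_cmn(rng, n):
    return build_cmn(rng.normal(size=n))


# -- average_roi_measurement -------------------------------------------------

def test_two_point_mean():
    parc = ROIParcellation(("a", "b"), vertex_assignment=np.array([0, 0, 1]))
    means = average_roi_measurement(np.array([2.0, 4.0, 7.0]), parc)
    assert means[0] == 3.0
    assert means[1] == 7.0


def test_constant_field():
    parc = ROIParcellation(("a", "b", "c"), vertex_assignment=np.array([0, 1, 2, 0, 1, 2]))
    means = average_roi_measurement(np.full(6, 1.25), parc)
    assert np.all(means == 1.25)


def test_matches_bruteforce_loop(rng):
    assignment = rng.integers(0, 3, size=100)
    assignment[:3] = [0, 1, 2]  # every ROI populated
    values = rng.normal(size=100)
    parc = ROIParcellation(("r0", "r1", "r2"), vertex_assignment=assignment)
    means = average_roi_measurement(values, parc)
    for roi in range(3):
        total, count = 0.0, 0
        for v, a in zip(values, assignment):
            if a == roi:
                total, count = total + v, count + 1
        assert means[roi] == pytest.approx(total / count, abs=1e-12)


def test_empty_roi_is_named_error():
    parc = ROIParcellation(("good", "empty"), vertex_assignment=np.array([0, 0]))
    with pytest.raises(CMNValidationError, match="empty"):
        average_roi_measurement(np.array([1.0, 2.0]), parc)


# -- build_cmn ---------------------------------------------------------------

def test_hand_computed_matrix():
    matrix = build_cmn(np.array([1.0, 1.0, 2.0]))
    assert np.array_equal(matrix, np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float))


def test_identical_means_give_zero_matrix():
    assert np.all(build_cmn(np.full(5, 3.7)) == 0.0)


def test_nonfinite_rejected():
    with pytest.raises(CMNValidationError):
        build_cmn(np.array([1.0, np.nan]))


@settings(max_examples=30, deadline=None)
@given(finite_means, st.floats(min_value=-100, max_value=100, allow_nan=False))
def test_translation_invariance(means, c):
    means = np.asarray(means)
    assert np.allclose(build_cmn(means + c), build_cmn(means), atol=1e-6)


@settings(max_examples=30, deadline=None)
@given(finite_means, st.floats(min_value=-10, max_value=10, allow_nan=False))
def test_scale_equivariance(means, a):
    means = np.asarray(means)
    assert np.allclose(build_cmn(a * means), abs(a) * build_cmn(means), rtol=1e-9, atol=1e-9)


@settings(max_examples=30, deadline=None)
@given(finite_means)
def test_structural_invariants(means):
    matrix = build_cmn(np.asarray(means))
    assert np.array_equal(matrix, matrix.T)
    assert np.all(np.diagonal(matrix) == 0.0)
    assert np.all(matrix >= 0.0)


# -- EdgeIndexMap / vectorization -------------------------------------------

def test_dk_scale_vector_length():
    assert len(EdgeIndexMap(35)) == 595


def test_three_roi_vector_length():
    assert len(EdgeIndexMap(3)) == 3


def test_pair_order_row_major():
    emap = EdgeIndexMap(4)
    assert emap.pairs == ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    for p, (i, j) in enumerate(emap.pairs):
        assert emap.index(i, j) == p
        assert emap.index(j, i) == p
    with pytest.raises(CMNValidationError):
        emap.index(2, 2)


def test_roundtrip_exact(rng):
    emap = EdgeIndexMap(9)
    matrix = random_cmn(rng, 9)
    assert np.array_equal(devectorize_cmn(vectorize_cmn(matrix, emap), emap), matrix)


def test_vectorize_rejects_invalid():
    bad = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(CMNValidationError, match="symmetric"):
        vectorize_cmn(bad)
    with pytest.raises(CMNValidationError, match="diagonal"):
        vectorize_cmn(np.array([[1.0, 2.0], [2.0, 0.0]]))


# -- build_feature_table -----------------------------------------------------

def _table(values, roi_names=("a", "b", "c")):
    n = np.asarray(values).shape[0]
    return CorticalAttributeTable(
        measurement="cortical_thickness",
        hemisphere="lh",
        values=values,
        labels=np.array(["x"] * (n // 2) + ["y"] * (n - n // 2)),
        subjects=[f"s{i}" for i in range(n)],
        roi_names=roi_names,
    )


def test_feature_table_hand_computed():
    table = _table(np.array([[0.0, 1.0, 3.0], [2.0, 2.0, 2.0]]))
    features = build_feature_table(table)
    assert np.array_equal(features, np.array([[1.0, 3.0, 2.0], [0.0, 0.0, 0.0]]))


def test_feature_table_dk_has_595_columns(rng):
    names = tuple(f"r{i}" for i in range(35))
    table = _table(rng.normal(size=(4, 35)), roi_names=names)
    assert build_feature_table(table).shape == (4, 595)


def test_permutation_oracle(rng):
    """Permuting ROI order permutes columns per the permuted index map."""
    n_r = 7
    values = rng.normal(size=(5, n_r))
    perm = rng.permutation(n_r)
    names = tuple(f"r{i}" for i in range(n_r))
    base = build_feature_table(_table(values, roi_names=names))
    permuted = build_feature_table(
        _table(values[:, perm], roi_names=tuple(names[p] for p in perm))
    )
    emap = EdgeIndexMap(n_r)
    inv = np.empty(n_r, dtype=int)
    inv[perm] = np.arange(n_r)
    for p, (i, j) in enumerate(emap.pairs):
        q = emap.index(inv[i], inv[j])
        assert np.array_equal(permuted[:, q], base[:, p])


# -- I/O ---------------------------------------------------------------------

def test_tidy_roundtrip(tmp_path, small_cohort):
    path = tmp_path / "cohort.csv"
    small_cohort.write_csv(path)
    tables = read_tidy_csv(path)
    key = ("cortical_thickness", "lh")
    original = small_cohort.tables[key]
    loaded = tables[key]
    assert loaded.subjects == original.subjects
    assert np.allclose(loaded.values, original.values)
    assert np.array_equal(loaded.labels.astype(str), original.labels.astype(str))


def test_tidy_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("subject_id,value\ns1,0.5\n")
    with pytest.raises(CMNValidationError, match="missing columns"):
        read_tidy_csv(path)


def test_aparc_stats_reader(tmp_path):
    path = tmp_path / "lh.aparc.stats"
    path.write_text(
        "# Table of FreeSurfer cortical parcellation anatomical statistics\n"
        "# some other comment\n"
        "# ColHeaders StructName NumVert ThickAvg MeanCurv\n"
        "bankssts 1400 2.51 0.12\n"
        "insula 2200 3.01 0.11\n"
    )
    frame = read_aparc_stats(path)
    assert list(frame.index) == ["bankssts", "insula"]
    assert frame.loc["insula", "ThickAvg"] == pytest.approx(3.01)


def test_aparc_stats_header_row(tmp_path):
    path = tmp_path / "plain.stats"
    path.write_text("StructName ThickAvg\n# stray comment\nfoo 1.5\n")
    frame = read_aparc_stats(path)
    assert frame.loc["foo", "ThickAvg"] == pytest.approx(1.5)


def test_tables_to_tidy_frame_columns(small_cohort):
    frame = tables_to_tidy_frame(small_cohort.tables)
    assert list(frame.columns) == [
        "subject_id", "group", "hemisphere", "measurement", "roi_name", "value",
    ]
    assert len(frame) == 40 * 6
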