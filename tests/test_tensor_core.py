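"""Tensor loading, flattening, similarity and heterogeneity."""

import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recticluster import tensor_core as tc

from conftest import long_rows, make_tensor


def _csv(shape, axis_names, values, drop=None, dup=None, mangle_value=None):
    rows = list(long_rows(shape, axis_names, values))
    if drop is not None:
        rows.pop(drop)
    if dup is not None:
        rows.append(rows[dup])
    header = ",".join(list(axis_names) + ["value"])
    lines = [header]
    for i, r in enumerate(rows):
        val = mangle_value if mangle_value is not None and i == 1 else r[-1]
        lines.append(",".join(list(map(str, r[:-1])) + [str(val)]))
    return io.StringIO("\n".join(lines))


class TestLoadLongTable:
    @pytest.mark.parametrize(
        "shape,axis_names",
        [
            ((10, 5, 3), ("cell_line", "ligand", "time")),
            ((1,), ("only",)),
            ((3, 2, 2, 2), ("a", "b", "c", "d")),
        ],
    )
    def test_round_trip_shapes_and_lookup(self, shape, axis_names):
        rng = np.random.default_rng(1)
        v = rng.random(shape)
        Z = tc.load_long_table(_csv(shape, axis_names, v), axis_names)
        assert Z.shape == shape
        assert Z.axis_names == tuple(axis_names)
        np.testing.assert_allclose(Z.values, v)
        # entry lookup by label tuple matches the source row
        idx = tuple(1 % s for s in shape)
        labels = tuple(Z.labels(n)[i] for n, i in zip(axis_names, idx))
        assert Z.get(labels) == pytest.approx(v[idx])

    def test_missing_combination_names_first_absent_tuple(self):
        stream = _csv((2, 2), ("a", "b"), np.arange(4.0), drop=1)
        with pytest.raises(tc.TensorError, match="incomplete.*a0.*b1"):
            tc.load_long_table(stream, ("a", "b"))

    def test_duplicate_combination_rejected(self):
        stream = _csv((2, 2), ("a", "b"), np.arange(4.0), dup=0)
        with pytest.raises(tc.TensorError, match="duplicate"):
            tc.load_long_table(stream, ("a", "b"))

    def test_non_numeric_value_reports_row(self):
        stream = _csv((2, 2), ("a", "b"), np.arange(4.0), mangle_value="oops")
        with pytest.raises(tc.TensorError, match="row 3"):
            tc.load_long_table(stream, ("a", "b"))


class TestFlatten:
    @pytest.mark.parametrize(
        "shape,d,expected",
        [((10, 5, 3), 2, (50, 3)), ((2, 2), 1, (2, 2)), ((6, 5, 4, 3), 2, (30, 12))],
    )
    def test_flat_shape(self, shape, d, expected):
        M = tc.flatten(make_tensor(shape), d)
        assert M.values.shape == expected
        assert len(M.row_index) == expected[0]

    def test_matrix_flatten_is_identity(self):
        Z = make_tensor((2, 2))
        np.testing.assert_array_equal(tc.flatten(Z, 1).values, Z.values)

    def test_rows_are_row_major_slices(self):
        Z = make_tensor((3, 2, 4))
        M = tc.flatten(Z, 2)
        np.testing.assert_array_equal(M.values[1 * 2 + 1], Z.values[1, 1])
        assert M.row_index[3] == (Z.labels("ax0")[1], Z.labels("ax1")[1])

    def test_preserves_value_multiset_and_count(self):
        Z = make_tensor((4, 3, 2))
        M = tc.flatten(Z, 1)
        assert M.values.size == Z.values.size
        np.testing.assert_allclose(
            np.sort(M.values.ravel()), np.sort(Z.values.ravel())
        )

    @pytest.mark.parametrize("d", [0, 3, -1])
    def test_d_out_of_range(self, d):
        with pytest.raises(tc.TensorError):
            tc.flatten(make_tensor((2, 2, 2)), d)


class TestNormalizeRows:
    def test_unit_l2_pythagorean_row(self):
        M = tc.FlatMatrix(np.array([[3.0, 4.0]]), (("e",),), (("t0",), ("t1",)))
        np.testing.assert_allclose(
            tc.normalize_rows(M, "unit-l2").values, [[0.6, 0.8]]
        )

    def test_max1(self):
        M = tc.FlatMatrix(np.array([[2.0, 4.0]]), (("e",),), (("t0",), ("t1",)))
        np.testing.assert_allclose(tc.normalize_rows(M, "max1").values, [[0.5, 1.0]])

    def test_unit_l2_idempotent(self):
        M = tc.FlatMatrix(
            np.array([[0.6, 0.8], [1.0, 0.0]]), (("a",), ("b",)), (("x",), ("y",))
        )
        once = tc.normalize_rows(M, "unit-l2")
        np.testing.assert_allclose(tc.normalize_rows(once, "unit-l2").values,
                                   once.values)

    def test_zero_row_identifies_experiment(self):
        M = tc.FlatMatrix(
            np.array([[1.0, 1.0], [0.0, 0.0]]),
            (("c0", "l0"), ("c0", "l1")),
            (("x",), ("y",)),
        )
        with pytest.raises(tc.TensorError, match="l1"):
            tc.normalize_rows(M, "unit-l2")


class TestCosineSimilarity:
    def test_hand_oracle_values(self):
        M = tc.FlatMatrix(
            np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [2.0, 2.0]]),
            tuple((f"e{i}",) for i in range(4)),
            (("x",), ("y",)),
        )
        S = tc.cosine_similarity(M).values
        assert S[0, 1] == pytest.approx(0.0, abs=1e-12)  # orthogonal
        assert S[2, 3] == pytest.approx(1.0, abs=1e-12)  # collinear
        assert S[0, 2] == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_symmetric_unit_diagonal_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        M = tc.flatten(make_tensor((4, 3, 5), seed=seed), 2)
        S = tc.cosine_similarity(M).values
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-12)
        assert S.min() >= 0.0 and S.max() <= 1.0  # non-negative inputs


class TestSimilarityTensorRoundTrip:
    @pytest.mark.parametrize("dims", [(10, 5), (2, 3), (6, 5, 4, 3)[:2], (4,)])
    def test_unflatten_then_flatten_identity(self, dims):
        n1 = int(np.prod(dims))
        rng = np.random.default_rng(0)
        A = rng.random((n1, n1))
        S_mat = tc.SimilarityMatrix((A + A.T) / 2, tuple((str(i),) for i in range(n1)))
        S = tc.unflatten_similarity(S_mat, dims)
        assert S.values.shape == tuple(dims) + tuple(dims)
        np.testing.assert_array_equal(tc.flatten_similarity(S).values, S_mat.values)

    def test_tensor_entries_match_matrix_by_rank(self):
        Z = make_tensor((3, 2, 4))
        S_mat, S = tc.similarity_from_tensor(Z, 2)
        for (a, (i1, i2)), (b, (j1, j2)) in itertools.product(
            enumerate(itertools.product(range(3), range(2))), repeat=2
        ):
            assert S.values[i1, i2, j1, j2] == S_mat.values[a, b]

    def test_dims_mismatch(self):
        S_mat = tc.SimilarityMatrix(np.eye(6), tuple((str(i),) for i in range(6)))
        with pytest.raises(tc.TensorError, match="mismatch"):
            tc.unflatten_similarity(S_mat, (2, 2))

    def test_symmetry_in_multi_index_pairs(self):
        Z = make_tensor((3, 2, 5), seed=4)
        _, S = tc.similarity_from_tensor(Z, 2)
        np.testing.assert_allclose(
            S.values, np.transpose(S.values, (2, 3, 0, 1)), atol=1e-12
        )


class TestHeterogeneityScore:
    def _sim(self, rows):
        M = tc.FlatMatrix(
            np.asarray(rows, dtype=float),
            tuple((f"e{i}",) for i in range(len(rows))),
            tuple((f"t{j}",) for j in range(len(rows[0]))),
        )
        return tc.cosine_similarity(M)

    def test_identical_rows_score_zero(self):
        S = self._sim([[1, 2], [1, 2], [2, 4]])
        assert tc.heterogeneity_score(S, [0, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_rows_score_one(self):
        S = self._sim([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
        assert tc.heterogeneity_score(S, [0, 1, 2]) == pytest.approx(1.0)

    def test_pair_mean_oracle(self):
        # pairwise similarities {1.0, 0.5, 0.5} -> mean(0, 0.5, 0.5) = 1/3
        vals = np.array([[1, 1, 0.5], [1, 1, 0.5], [0.5, 0.5, 1.0]])
        S = tc.SimilarityMatrix(vals, (("a",), ("b",), ("c",)))
        assert tc.heterogeneity_score(S, [0, 1, 2]) == pytest.approx(1 / 3)

    def test_relabelling_invariance_and_range(self):
        S = self._sim(np.random.default_rng(7).random((6, 4)))
        a = tc.heterogeneity_score(S, [0, 2, 4])
        b = tc.heterogeneity_score(S, [4, 0, 2])
        assert a == b and 0.0 <= a <= 1.0

    def test_singleton_rejected(self):
        S = self._sim([[1, 0], [0, 1]])
        with pytest.raises(tc.TensorError, match="at least two"):
            tc.heterogeneity_score(S, [0])

    def test_negative_similarity_rejected(self):
        vals = np.array([[1.0, -0.5], [-0.5, 1.0]])
        S = tc.SimilarityMatrix(vals, (("a",), ("b",)))
        with pytest.raises(tc.TensorError, match="non-negative"):
            tc.heterogeneity_score(S, [0, 1])


def test_similarity_csv_round_trip(tmp_path):
    Z = make_tensor((2, 3, 4), seed=2)
    S_mat, _ = tc.similarity_from_tensor(Z, 2)
    path = tmp_path / "sim.csv"
    tc.save_similarity_csv(S_mat, path)
    loaded = tc.load_similarity_csv(path)
    assert loaded.index == S_mat.index
    np.testing.assert_allclose(loaded.values, S_mat.values, atol=1e-12)


def test_incomplete_tensor_is_hard_error():
    v = np.ones((2, 2))
    v[0, 1] = np.nan
    with pytest.raises(tc.TensorError, match="non-finite"):
        tc.DataTensor(v, (("a", ("a0", "a1")), ("b", ("b0", "b1"))))
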