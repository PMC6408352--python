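"""Multi-indexed data tensors: loading, flattening, similarity, heterogeneity.

A complete multi-indexed dataset (e.g. cell line x ligand x dose x time x
protein phosphorylation measurements) is held as a dense order-``h`` tensor
with named, labelled axes.  Flattening the first ``d`` axes into rows gives an
``N1 x N2`` experiment-by-feature matrix; cosine similarity between rows gives
an ``N1 x N1`` similarity matrix, which reverse-flattens into an order-``2d``
similarity tensor indexed by pairs of experiment multi-indices.  All
flattenings use row-major (last-axis-fastest) enumeration, fixed so the
matrix <-> tensor correspondence is bit-stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine


class TensorError(ValueError):
    """Raised for malformed or incomplete data tensors."""


@dataclass(frozen=True)
class DataTensor:
    """Dense, complete real tensor with named and labelled axes."""

    values: np.ndarray
    axes: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        axes = tuple((str(n), tuple(str(x) for x in labs)) for n, labs in self.axes)
        object.__setattr__(self, "axes", axes)
        if v.ndim != len(axes):
            raise TensorError(
                f"tensor order {v.ndim} does not match {len(axes)} axis specs"
            )
        for dim, (name, labels) in zip(v.shape, axes):
            if len(labels) != dim:
                raise TensorError(
                    f"axis {name!r}: {len(labels)} labels for dimension of size {dim}"
                )
            if len(set(labels)) != len(labels):
                raise TensorError(f"axis {name!r} has duplicate labels")
        if not np.all(np.isfinite(v)):
            raise TensorError("incomplete tensor: non-finite entries present")

    @property
    def order(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.axes)

    def labels(self, axis: str) -> tuple[str, ...]:
        for name, labs in self.axes:
            if name == axis:
                return labs
        raise KeyError(axis)

    def get(self, label_tuple: Sequence[str]) -> float:
        """Entry lookup by one label per axis."""
        if len(label_tuple) != self.order:
            raise TensorError("label tuple length must equal tensor order")
        idx = tuple(
            labs.index(str(lab)) for (_, labs), lab in zip(self.axes, label_tuple)
        )
        return float(self.values[idx])


@dataclass(frozen=True)
class FlatMatrix:
    """Flattened tensor: rows indexed by the leading ``d`` axes' label tuples."""

    values: np.ndarray
    row_index: tuple[tuple[str, ...], ...]
    col_index: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.row_index), len(self.col_index)):
            raise TensorError("flat matrix shape does not match its indices")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise-similarity matrix over experiment multi-indices."""

    values: np.ndarray
    index: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.index)
        if v.shape != (n, n):
            raise TensorError("similarity matrix must be square over its index")
        if not np.allclose(v, v.T, atol=1e-9):
            raise TensorError("similarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.index)


@dataclass(frozen=True)
class SimilarityTensor:
    """Order-2d similarity tensor; entry ((i),(j)) = similarity of experiments."""

    values: np.ndarray
    dims: tuple[int, ...]
    index: tuple[tuple[str, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        d = len(self.dims)
        if v.shape != tuple(self.dims) + tuple(self.dims):
            raise TensorError(
                f"similarity tensor shape {v.shape} inconsistent with dims {self.dims}"
            )
        object.__setattr__(self, "dims", tuple(int(x) for x in self.dims))

    @property
    def d(self) -> int:
        return len(self.dims)


def load_long_table(
    stream,
    axis_names: Sequence[str],
    value_column: str = "value",
    sep: str | None = None,
) -> DataTensor:
    """Read a long-format delimited table into a complete :class:`DataTensor`.

    Each row carries one label per axis plus a numeric value; every
    combination of labels must appear exactly once.  Axis label order is the
    order of first appearance in the file.
    """
    df = pd.read_csv(stream, sep=sep, engine="python" if sep is None else "c",
                     dtype=str)
    missing_cols = [c for c in list(axis_names) + [value_column] if c not in df.columns]
    if missing_cols:
        raise TensorError(f"missing columns in input table: {missing_cols}")

    vals = pd.to_numeric(df[value_column], errors="coerce")
    bad = np.where(~np.isfinite(vals.to_numpy()))[0]
    if bad.size:
        # +2: header line plus 1-based numbering
        raise TensorError(
            f"non-numeric or non-finite value at data row {bad[0] + 2}: "
            f"{df[value_column].iloc[bad[0]]!r}"
        )

    labels: list[tuple[str, ...]] = []
    positions = np.empty((len(df), len(axis_names)), dtype=np.intp)
    for a, name in enumerate(axis_names):
        col = df[name].astype(str)
        uniq = tuple(dict.fromkeys(col))  # first-appearance order
        lut = {lab: i for i, lab in enumerate(uniq)}
        labels.append(uniq)
        positions[:, a] = col.map(lut).to_numpy()

    shape = tuple(len(u) for u in labels)
    n_expected = int(np.prod(shape))
    flat_pos = np.ravel_multi_index(positions.T, shape)
    counts = np.bincount(flat_pos, minlength=n_expected)
    if np.any(counts > 1):
        dup = int(np.argmax(counts > 1))
        tup = tuple(labels[a][i] for a, i in enumerate(np.unravel_index(dup, shape)))
        raise TensorError(f"duplicate combination {tup}")
    if np.any(counts == 0):
        first = int(np.argmax(counts == 0))
        tup = tuple(labels[a][i] for a, i in enumerate(np.unravel_index(first, shape)))
        raise TensorError(f"incomplete tensor: missing combination {tup}")

    arr = np.empty(n_expected, dtype=float)
    arr[flat_pos] = vals.to_numpy(dtype=float)
    return DataTensor(
        values=arr.reshape(shape),
        axes=tuple((name, labs) for name, labs in zip(axis_names, labels)),
    )


def _multi_index(axes: Sequence[tuple[str, tuple[str, ...]]]) -> tuple[tuple[str, ...], ...]:
    """Row-major enumeration of the Cartesian product of axis labels."""
    return tuple(itertools.product(*(labs for _, labs in axes)))


def flatten(Z: DataTensor, d: int) -> FlatMatrix:
    """Reshape the leading ``d`` axes into rows (row-major on both sides)."""
    if not 1 <= d < Z.order:
        raise TensorError(f"d={d} out of range for order-{Z.order} tensor")
    n1 = int(np.prod(Z.shape[:d]))
    n2 = int(np.prod(Z.shape[d:]))
    return FlatMatrix(
        values=Z.values.reshape(n1, n2),
        row_index=_multi_index(Z.axes[:d]),
        col_index=_multi_index(Z.axes[d:]),
    )


def normalize_rows(M: FlatMatrix, method: str = "unit-l2") -> FlatMatrix:
    """Normalize each experiment row.

    ``unit-l2`` divides by the Euclidean norm (so cosine similarity of the
    result equals a plain dot product), ``max1`` by the maximum absolute
    entry, ``none`` is the identity.
    """
    if method == "none":
        return M
    v = M.values
    if method == "unit-l2":
        scale = np.linalg.norm(v, axis=1)
    elif method == "max1":
        scale = np.max(np.abs(v), axis=1)
    else:
        raise TensorError(f"unknown normalization method {method!r}")
    zero = np.where(scale == 0)[0]
    if zero.size:
        raise TensorError(
            f"all-zero row for experiment {M.row_index[zero[0]]}: cannot normalize"
        )
    return FlatMatrix(values=v / scale[:, None], row_index=M.row_index,
                      col_index=M.col_index)


def cosine_similarity(M: FlatMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarity between experiment rows."""
    norms = np.linalg.norm(M.values, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise TensorError(
            f"all-zero row for experiment {M.row_index[zero[0]]}: "
            "cosine similarity undefined"
        )
    s = _sk_cosine(M.values)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    np.clip(s, -1.0, 1.0, out=s)
    return SimilarityMatrix(values=s, index=M.row_index)


def unflatten_similarity(S_mat: SimilarityMatrix, dims: Sequence[int]) -> SimilarityTensor:
    """Reverse-flatten an ``N1 x N1`` similarity matrix into an order-2d tensor."""
    dims = tuple(int(x) for x in dims)
    n1 = int(np.prod(dims))
    if S_mat.n != n1:
        raise TensorError(
            f"dimension mismatch: matrix is {S_mat.n}x{S_mat.n}, prod(dims)={n1}"
        )
    return SimilarityTensor(
        values=S_mat.values.reshape(dims + dims), dims=dims, index=S_mat.index
    )


def flatten_similarity(S: SimilarityTensor) -> SimilarityMatrix:
    """Inverse of :func:`unflatten_similarity`."""
    n1 = int(np.prod(S.dims))
    return SimilarityMatrix(
        values=S.values.reshape(n1, n1),
        index=S.index if S.index else tuple((str(i),) for i in range(n1)),
    )


def similarity_from_tensor(
    Z: DataTensor, d: int, normalization: str = "unit-l2"
) -> tuple[SimilarityMatrix, SimilarityTensor]:
    """Convenience: flatten, normalize, cosine, reverse-flatten in one call."""
    M = normalize_rows(flatten(Z, d), normalization)
    S_mat = cosine_similarity(M)
    return S_mat, unflatten_similarity(S_mat, Z.shape[:d])


def heterogeneity_score(S_mat: SimilarityMatrix, subset: Sequence[int]) -> float:
    """Within-group heterogeneity in [0, 1].

    Mean over unordered distinct pairs in ``subset`` of (1 - similarity):
    0 means complete homogeneity (all pairwise similarities 1), 1 complete
    heterogeneity (all pairwise similarities 0).  Requires non-negative
    similarities, i.e. non-negative source data.  Self-pairs are excluded
    because self-similarity is identically 1 and would only dilute the score.
    """
    subset = [int(i) for i in subset]
    if len(set(subset)) != len(subset):
        raise TensorError("subset contains repeated indices")
    if len(subset) < 2:
        raise TensorError("heterogeneity score needs at least two experiments")
    sub = S_mat.values[np.ix_(subset, subset)]
    off = sub[np.triu_indices(len(subset), k=1)]
    if np.any(off < -1e-12):
        raise TensorError(
            "negative similarity in subset: the score is defined for "
            "non-negative data only (use non-negative measurements)"
        )
    return float(np.mean(1.0 - np.clip(off, 0.0, 1.0)))


def save_similarity_csv(S_mat: SimilarityMatrix, path) -> None:
    """Write a similarity matrix with '|'-joined multi-index labels as headers."""
    names = ["|".join(t) for t in S_mat.index]
    pd.DataFrame(S_mat.values, index=names, columns=names).to_csv(path)


def load_similarity_csv(path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    index = tuple(tuple(str(c).split("|")) for c in df.index)
    return SimilarityMatrix(values=df.to_numpy(dtype=float), index=index)
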