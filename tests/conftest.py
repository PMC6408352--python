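"""Shared fixtures: small tensors, worked similarity instances, helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from recticluster.rect_partition import RectangularPartition
from recticluster.tensor_core import DataTensor


def long_rows(shape, axis_names, values):
    """Yield (labels..., value) rows for a dense tensor in row-major order."""
    labels = [tuple(f"{n}{i}" for i in range(s)) for n, s in zip(axis_names, shape)]
    flat = np.asarray(values).reshape(-1)
    for pos, idx in enumerate(itertools.product(*(range(s) for s in shape))):
        yield tuple(labels[a][i] for a, i in enumerate(idx)) + (flat[pos],)


def make_tensor(shape, seed=0, nonneg=True) -> DataTensor:
    rng = np.random.default_rng(seed)
    v = rng.random(shape) if nonneg else rng.normal(size=shape)
    axes = tuple(
        (f"ax{a}", tuple(f"ax{a}_{i}" for i in range(s)))
        for a, s in enumerate(shape)
    )
    return DataTensor(values=v, axes=axes)


@pytest.fixture
def orthogonal_rows_similarity() -> np.ndarray:
    """2x2 grid: similarity 1 within each row of cells, 0 across rows."""
    S = np.zeros((2, 2, 2, 2))
    for i1, i2, j1, j2 in itertools.product(range(2), repeat=4):
        S[i1, i2, j1, j2] = 1.0 if i1 == j1 else 0.0
    return S


@pytest.fixture
def row_split_2x2() -> RectangularPartition:
    return RectangularPartition(
        (2, 2),
        ((frozenset({0}), frozenset({0, 1})), (frozenset({1}), frozenset({0, 1}))),
    )


def random_similarity_tensor(n1: int, n2: int, rng) -> np.ndarray:
    """Random symmetric similarity tensor with unit diagonal, entries in [0,1]."""
    N = n1 * n2
    M = rng.random((N, N))
    S = (M + M.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S.reshape(n1, n2, n1, n2)


def rand_index(a, b) -> float:
    from sklearn.metrics import rand_score

    return float(rand_score(np.asarray(a).ravel(), np.asarray(b).ravel()))
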