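"""Rectangular partitions of a grid and their algebraic encodings.

A *rectangular* partition of an ``n1 x n2`` grid (cell lines x ligands) is a
hard partition in which every cluster is the Cartesian product of a row
subset and a column subset — possibly non-contiguous, since no ordering of
rows or columns is assumed.  Rectangularity is the interpretability
constraint: if two experiments (c_h, l_i) and (c_k, l_j) share a cluster and
hence a putative mechanism, the swapped combinations (c_k, l_i) and
(c_h, l_j) must share it too.

Two algebraic encodings are supported:

* ``X`` — a Boolean order-4 "distance" tensor with x[i1,i2,j1,j2] = 0 iff the
  two cells share a cluster, constrained by the equivalence-relation
  inequalities (reflexivity, symmetry, transitivity) plus three rectangularity
  families.
* ``Y``/``W`` — a one-hot ``n1 x n2 x m`` assignment tensor; W (a seed
  clustering) satisfies only unique assignment, Y additionally satisfies the
  rectangle-closure interpretability condition.

They are linked entrywise by ``1 - x_ij = sum_k y_ik y_jk``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

ORACLE_CELL_LIMIT = 12  # brute-force enumeration guard


class PartitionError(ValueError):
    """Raised for invalid partitions or encodings."""


@dataclass(frozen=True)
class RectangularPartition:
    """Hard partition of an n1 x n2 grid into rectangular clusters."""

    grid_shape: tuple[int, int]
    clusters: tuple[tuple[frozenset[int], frozenset[int]], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        gs = (int(self.grid_shape[0]), int(self.grid_shape[1]))
        object.__setattr__(self, "grid_shape", gs)
        cl = tuple(
            (frozenset(int(r) for r in rows), frozenset(int(c) for c in cols))
            for rows, cols in self.clusters
        )
        object.__setattr__(self, "clusters", cl)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(str(i) for i in range(len(cl)))
            )

    @property
    def m(self) -> int:
        return len(self.clusters)

    def cells(self, k: int) -> set[tuple[int, int]]:
        rows, cols = self.clusters[k]
        return {(r, c) for r in rows for c in cols}

    def membership_grid(self) -> np.ndarray:
        """n1 x n2 integer array of cluster indices; -1 marks uncovered cells."""
        n1, n2 = self.grid_shape
        g = np.full((n1, n2), -1, dtype=int)
        for k, (rows, cols) in enumerate(self.clusters):
            for r in rows:
                for c in cols:
                    g[r, c] = k
        return g

    def canonical(self) -> "RectangularPartition":
        """Clusters reordered by their lexicographically smallest member cell."""
        n2 = self.grid_shape[1]
        keyed = sorted(
            self.clusters, key=lambda rc: min(r * n2 + c for r in rc[0] for c in rc[1])
        )
        return RectangularPartition(self.grid_shape, tuple(keyed))

    def same_partition(self, other: "RectangularPartition") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and set(self.canonical().clusters) == set(other.canonical().clusters)
        )


def validate_partition(P: RectangularPartition) -> list[str]:
    """Report every violated invariant; an empty list means the partition is valid.

    Checks: non-empty clusters, no overlap, full coverage, and that each
    cluster is a full Cartesian product (rectangularity).  Disconnected
    rectangles are explicitly allowed.
    """
    report: list[str] = []
    n1, n2 = P.grid_shape
    seen: dict[tuple[int, int], int] = {}
    for k, (rows, cols) in enumerate(P.clusters):
        if not rows or not cols:
            report.append(f"empty cluster {k}")
            continue
        if max(rows) >= n1 or min(rows) < 0 or max(cols) >= n2 or min(cols) < 0:
            report.append(f"cluster {k} references cells outside the grid")
            continue
        for cell in ((r, c) for r in rows for c in cols):
            if cell in seen:
                report.append(f"overlap: cell {cell} in clusters {seen[cell]} and {k}")
            seen[cell] = k
    uncovered = {(r, c) for r in range(n1) for c in range(n2)} - set(seen)
    if uncovered:
        report.append(f"coverage gap: cells {sorted(uncovered)} unassigned")
    return report


def partition_from_cells(
    grid_shape: tuple[int, int], classes: Sequence[set[tuple[int, int]]]
) -> RectangularPartition:
    """Build a partition from explicit cell classes, enforcing rectangularity."""
    clusters = []
    for cls in classes:
        rows = frozenset(r for r, _ in cls)
        cols = frozenset(c for _, c in cls)
        if len(cls) != len(rows) * len(cols):
            raise PartitionError(
                f"non-rectangular class: {sorted(cls)} is not "
                f"{sorted(rows)} x {sorted(cols)}"
            )
        clusters.append((rows, cols))
    P = RectangularPartition(tuple(grid_shape), tuple(clusters)).canonical()
    problems = validate_partition(P)
    if problems:
        raise PartitionError("; ".join(problems))
    return P


# ---------------------------------------------------------------------------
# X encoding (Boolean pairwise-distance tensor)
# ---------------------------------------------------------------------------

def partition_to_x(P: RectangularPartition) -> np.ndarray:
    """Encode P as the order-4 Boolean tensor x[i1,i2,j1,j2] (0 = same cluster)."""
    problems = validate_partition(P)
    if problems:
        raise PartitionError("; ".join(problems))
    g = P.membership_grid()
    x = (g[:, :, None, None] != g[None, None, :, :]).astype(np.int8)
    return x


def _check_equivalence(A: np.ndarray) -> None:
    """A is the N x N sameness matrix (1 - x flattened); raise on violations."""
    n = A.shape[0]
    if np.any(np.diag(A) != 1):
        i = int(np.argmax(np.diag(A) != 1))
        raise PartitionError(f"reflexivity violated at cell {i}: x_ii != 0")
    if np.any(A != A.T):
        i, j = np.argwhere(A != A.T)[0]
        raise PartitionError(f"symmetry violated for cells ({i},{j})")
    # transitivity: A_ij = A_jk = 1 but A_ik = 0
    reach = (A @ A > 0).astype(np.int8)
    bad = np.argwhere((reach == 1) & (A == 0))
    if bad.size:
        i, k = bad[0]
        j = int(np.argmax((A[i] == 1) & (A[:, k] == 1)))
        raise PartitionError(
            f"transitivity violated for triple ({i},{j},{k}): "
            f"x_ij=0, x_jk=0 but x_ik=1"
        )


def x_to_partition(x: np.ndarray) -> RectangularPartition:
    """Decode an X tensor into a rectangular partition.

    Raises if X is not a valid equivalence encoding or if any equivalence
    class fails the Cartesian-product (rectangularity) test.
    """
    x = np.asarray(x)
    if x.ndim != 4 or x.shape[:2] != x.shape[2:]:
        raise PartitionError(f"X must have shape (n1,n2,n1,n2); got {x.shape}")
    n1, n2 = x.shape[:2]
    n = n1 * n2
    A = (1 - x.reshape(n, n)).astype(np.int8)
    _check_equivalence(A)
    # equivalence classes via union of rows
    unassigned = set(range(n))
    classes = []
    while unassigned:
        i = min(unassigned)
        members = set(np.flatnonzero(A[i]).tolist())
        classes.append({(m // n2, m % n2) for m in members})
        unassigned -= members
    return partition_from_cells((n1, n2), classes)


# ---------------------------------------------------------------------------
# Y / W encoding (one-hot assignment tensor)
# ---------------------------------------------------------------------------

def partition_to_y(P: RectangularPartition, m: int | None = None) -> np.ndarray:
    """One-hot n1 x n2 x m assignment tensor; trailing slices padded with zeros."""
    if m is None:
        m = P.m
    if m < P.m:
        raise PartitionError(f"m={m} smaller than cluster count {P.m}")
    n1, n2 = P.grid_shape
    y = np.zeros((n1, n2, m), dtype=np.int8)
    g = P.membership_grid()
    if np.any(g < 0):
        raise PartitionError("partition does not cover the grid")
    for r in range(n1):
        for c in range(n2):
            y[r, c, g[r, c]] = 1
    return y


def y_to_partition(y: np.ndarray, require_rectangular: bool = True) -> RectangularPartition:
    """Decode an assignment tensor; empty (all-zero) slices are dropped.

    With ``require_rectangular`` each used slice must be an outer product of
    row/column indicator vectors (the interpretability condition).
    """
    y = np.asarray(y)
    if y.ndim != 3:
        raise PartitionError("Y must have shape (n1,n2,m)")
    if np.any(y.sum(axis=2) != 1):
        r, c = np.argwhere(y.sum(axis=2) != 1)[0]
        raise PartitionError(f"unique assignment violated at cell ({r},{c})")
    classes = []
    for k in range(y.shape[2]):
        cells = {(int(r), int(c)) for r, c in np.argwhere(y[:, :, k] == 1)}
        if not cells:
            continue
        if require_rectangular:
            rows = {r for r, _ in cells}
            cols = {c for _, c in cells}
            if len(cells) != len(rows) * len(cols):
                raise PartitionError(
                    f"slice {k} is not an outer-product (rectangular) pattern"
                )
        classes.append(cells)
    return partition_from_cells(y.shape[:2], classes)


def labels_to_w(labels: np.ndarray, m: int | None = None) -> np.ndarray:
    """n1 x n2 integer label grid -> n1 x n2 x m one-hot seed tensor W."""
    labels = np.asarray(labels, dtype=int)
    if m is None:
        m = int(labels.max()) + 1
    w = np.zeros(labels.shape + (m,), dtype=np.int8)
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            w[r, c, labels[r, c]] = 1
    return w


# ---------------------------------------------------------------------------
# Exhaustive oracle enumeration
# ---------------------------------------------------------------------------

def enumerate_rectangular_partitions(
    n1: int, n2: int
) -> Iterator[RectangularPartition]:
    """Yield every rectangular partition of the grid, each exactly once.

    Recursive construction: the cluster containing the smallest uncovered
    cell (row-major) is chosen as R x C over all row subsets R containing
    that cell's row and column subsets C containing its column whose product
    lies in the uncovered region; recursion covers the rest.  Clusters are
    therefore produced directly in canonical (smallest-cell) order.
    """
    if n1 * n2 > ORACLE_CELL_LIMIT:
        raise PartitionError(
            f"grid {n1}x{n2} exceeds the {ORACLE_CELL_LIMIT}-cell oracle limit"
        )

    all_cells = frozenset((r, c) for r in range(n1) for c in range(n2))

    def rec(uncovered: frozenset, acc: list):
        if not uncovered:
            yield RectangularPartition((n1, n2), tuple(acc))
            return
        r0, c0 = min(uncovered, key=lambda rc: rc[0] * n2 + rc[1])
        # rows/cols that could extend the pivot cell's cluster
        cand_rows = sorted({r for r, c in uncovered if c == c0 and r != r0})
        cand_cols = sorted({c for r, c in uncovered if r == r0 and c != c0})
        for nr in range(len(cand_rows) + 1):
            for rows_extra in itertools.combinations(cand_rows, nr):
                rows = frozenset((r0,) + rows_extra)
                for nc in range(len(cand_cols) + 1):
                    for cols_extra in itertools.combinations(cand_cols, nc):
                        cols = frozenset((c0,) + cols_extra)
                        block = {(r, c) for r in rows for c in cols}
                        if not block <= uncovered:
                            continue
                        acc.append((rows, cols))
                        yield from rec(uncovered - frozenset(block), acc)
                        acc.pop()

    yield from rec(all_cells, [])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def partition_to_frame(
    P: RectangularPartition,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format table with columns (row_label, col_label, cluster_id)."""
    n1, n2 = P.grid_shape
    row_labels = list(row_labels) if row_labels else [str(i) for i in range(n1)]
    col_labels = list(col_labels) if col_labels else [str(j) for j in range(n2)]
    g = P.membership_grid()
    recs = [
        (row_labels[r], col_labels[c], P.labels[g[r, c]])
        for r in range(n1)
        for c in range(n2)
    ]
    return pd.DataFrame(recs, columns=["row_label", "col_label", "cluster_id"])


def partition_from_frame(df: pd.DataFrame) -> tuple[RectangularPartition, list, list]:
    """Inverse of :func:`partition_to_frame` (labels in first-appearance order)."""
    rows = list(dict.fromkeys(df["row_label"].astype(str)))
    cols = list(dict.fromkeys(df["col_label"].astype(str)))
    rpos = {x: i for i, x in enumerate(rows)}
    cpos = {x: i for i, x in enumerate(cols)}
    groups: dict[str, set] = {}
    for _, rec in df.iterrows():
        groups.setdefault(str(rec["cluster_id"]), set()).add(
            (rpos[str(rec["row_label"])], cpos[str(rec["col_label"])])
        )
    P = partition_from_cells((len(rows), len(cols)), list(groups.values()))
    return P, rows, cols


def partition_to_json(
    P: RectangularPartition,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> str:
    n1, n2 = P.grid_shape
    row_labels = list(row_labels) if row_labels else [str(i) for i in range(n1)]
    col_labels = list(col_labels) if col_labels else [str(j) for j in range(n2)]
    out = {
        str(k): {
            "rows": sorted(row_labels[r] for r in rows),
            "cols": sorted(col_labels[c] for c in cols),
        }
        for k, (rows, cols) in enumerate(P.canonical().clusters)
    }
    return json.dumps({"grid_shape": [n1, n2], "clusters": out}, indent=2)
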