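"""Integer linear programs for rectangularity-constrained clustering.

Two exact formulations, both solved by branch and cut to a certified global
optimum (zero optimality gap by default):

* **direct** — maximize ``<S, 1-X> + lambda * <1, X>`` over Boolean pairwise
  "different cluster" indicators X, subject to the equivalence-relation
  (transitivity) inequalities and three rectangularity constraint families.
  ``lambda`` regularizes the number of clusters: larger values reward
  between-cluster pairs and hence finer partitions.
* **refine** — given a (possibly non-rectangular) one-hot seed clustering W,
  maximize the number of unchanged assignments ``<W, Y>`` over one-hot Y
  subject to unique assignment and the rectangle-closure interpretability
  condition.

The backend is any MILP solver supporting Boolean variables and two-sided
linear constraints; the bundled HiGHS branch-and-cut solver (via
``scipy.optimize.milp``) is the reference backend.  Transitivity rows can be
generated lazily (iterative violated-row addition), which reaches the same
certified optimum without materializing all O(N^3) rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linear_sum_assignment, milp

from .rect_partition import (
    ORACLE_CELL_LIMIT,
    PartitionError,
    RectangularPartition,
    enumerate_rectangular_partitions,
    partition_to_x,
    x_to_partition,
    y_to_partition,
)

LAZY_CELL_THRESHOLD = 60  # grids larger than this get lazy transitivity rows


class ProgramError(ValueError):
    """Raised for malformed program inputs."""


@dataclass
class IntegerProgram:
    """Boolean-variable ILP: maximize c.x + offset s.t. lb <= A x <= ub."""

    var_names: list[str]
    A: sp.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    objective: np.ndarray  # maximize-sense coefficients
    offset: float
    meta: dict = field(default_factory=dict)

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def n_nonzeros(self) -> int:
        return int(self.A.nnz)


@dataclass
class SolveResult:
    status: str  # optimal | infeasible | limit
    assignment: np.ndarray | None
    objective_value: float
    gap: float
    solver_log: str = ""


# ---------------------------------------------------------------------------
# Row-count bookkeeping
# ---------------------------------------------------------------------------

def written_row_count(n1: int, n2: int) -> int:
    """Constraint rows of the X-formulation counted as the families are stated.

    Reflexivity (N1), symmetry (N1^2 ordered pairs), transitivity (N1^3
    ordered triples) and the three rectangularity families (n1^2 n2^2 index
    tuples each), with N1 = n1*n2 and no deduplication.  For the 36 x 14
    problem this exceeds one million rows by two orders of magnitude.
    """
    N1 = n1 * n2
    return N1 + N1**2 + N1**3 + 3 * n1**2 * n2**2


def built_row_count(n1: int, n2: int, transitivity: str = "full") -> int:
    """Rows of the deduplicated pair-variable build (closed form)."""
    N = n1 * n2
    q = math.comb(n1, 2) * math.comb(n2, 2)
    rows = 5 * q  # 1 diagonal equality + 4 side inequalities per quadruple
    if transitivity == "full":
        rows += 3 * math.comb(N, 3)
    return rows


def refine_row_count(n1: int, n2: int, m: int, as_written: bool = True) -> int:
    """Interpretability rows of the Y-formulation (excluding assignment rows)."""
    if as_written:
        return n1**2 * n2**2 * m
    return n1 * (n1 - 1) * n2 * (n2 - 1) * m


# ---------------------------------------------------------------------------
# Direct formulation (Boolean pairwise X)
# ---------------------------------------------------------------------------

def _pair_layout(N: int) -> tuple[dict[tuple[int, int], int], list[tuple[int, int]]]:
    pairs = [(a, b) for a in range(N) for b in range(a + 1, N)]
    return {p: i for i, p in enumerate(pairs)}, pairs


def _as_similarity_array(S) -> np.ndarray:
    values = getattr(S, "values", S)
    v = np.asarray(values, dtype=float)
    if v.ndim != 4 or v.shape[:2] != v.shape[2:]:
        raise ProgramError(f"similarity tensor must be (n1,n2,n1,n2); got {v.shape}")
    return v


def build_direct_program(S, lam: float, transitivity: str = "auto") -> IntegerProgram:
    """Build the direct clustering ILP from an order-4 similarity tensor.

    One Boolean variable per unordered pair of distinct grid cells;
    reflexivity and symmetry are enforced structurally.  ``transitivity`` is
    ``"full"``, ``"lazy"`` (rows added during solving as they are violated)
    or ``"auto"`` (lazy above ``LAZY_CELL_THRESHOLD`` cells).
    """
    v = _as_similarity_array(S)
    if lam < 0:
        raise ProgramError("lambda must be non-negative")
    n1, n2 = v.shape[:2]
    N = n1 * n2
    Smat = v.reshape(N, N)
    if not np.allclose(Smat, Smat.T, atol=1e-9):
        raise ProgramError("similarity tensor is not symmetric in its index pairs")
    if transitivity == "auto":
        transitivity = "lazy" if N > LAZY_CELL_THRESHOLD else "full"

    pidx, pairs = _pair_layout(N)
    nv = len(pairs)

    rows_i: list[int] = []
    cols_i: list[int] = []
    data: list[float] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def add_row(terms: Sequence[tuple[int, float]], lo: float, hi: float) -> None:
        r = len(lbs)
        for var, coef in terms:
            rows_i.append(r)
            cols_i.append(var)
            data.append(coef)
        lbs.append(lo)
        ubs.append(hi)

    # Rectangularity: for each row pair i1<j1 and column pair i2<j2, the four
    # cells a=(i1,i2) b=(i1,j2) c=(j1,i2) d=(j1,j2) obey
    #   x_ad = x_bc  (diagonal equality)
    #   x_ad >= x_ab, x_ad >= x_cd (same-row sides)
    #   x_ad >= x_ac, x_ad >= x_bd (same-column sides)
    for i1 in range(n1):
        for j1 in range(i1 + 1, n1):
            for i2 in range(n2):
                for j2 in range(i2 + 1, n2):
                    a = i1 * n2 + i2
                    b = i1 * n2 + j2
                    c = j1 * n2 + i2
                    d = j1 * n2 + j2
                    ad = pidx[(a, d)]
                    bc = pidx[(b, c)]
                    add_row([(ad, 1.0), (bc, -1.0)], 0.0, 0.0)
                    for side in ((a, b), (c, d), (a, c), (b, d)):
                        add_row([(ad, 1.0), (pidx[side], -1.0)], 0.0, 1.0)

    if transitivity == "full":
        for a in range(N):
            for b in range(a + 1, N):
                ab = pidx[(a, b)]
                for c in range(b + 1, N):
                    ac = pidx[(a, c)]
                    bc = pidx[(b, c)]
                    add_row([(ab, 1.0), (bc, 1.0), (ac, -1.0)], 0.0, 2.0)
                    add_row([(ab, 1.0), (ac, 1.0), (bc, -1.0)], 0.0, 2.0)
                    add_row([(ac, 1.0), (bc, 1.0), (ab, -1.0)], 0.0, 2.0)

    A = sp.csr_matrix(
        (data, (rows_i, cols_i)), shape=(len(lbs), nv)
    )
    # maximize  sum_{ordered i!=j} [S_ij (1 - x) + lam x] + sum_i S_ii
    #        =  C0 + sum_pairs (2 lam - s2_p) x_p
    s2 = np.array([Smat[a, b] + Smat[b, a] for a, b in pairs])
    obj = 2.0 * lam - s2
    offset = float(np.trace(Smat) + s2.sum())
    return IntegerProgram(
        var_names=[f"x_{a}_{b}" for a, b in pairs],
        A=A,
        lb=np.array(lbs),
        ub=np.array(ubs),
        objective=obj,
        offset=offset,
        meta={
            "kind": "direct",
            "grid_shape": (n1, n2),
            "lambda": float(lam),
            "transitivity": transitivity,
            "pairs": pairs,
        },
    )


def _violated_transitivity_rows(
    x: np.ndarray, pidx: dict, N: int
) -> list[tuple[int, int, int]]:
    """Find triples whose transitivity inequality the incumbent violates."""
    A = np.zeros((N, N), dtype=np.int8)
    for (a, b), k in pidx.items():
        A[a, b] = A[b, a] = 1 - int(round(x[k]))
    np.fill_diagonal(A, 1)
    viol = []
    # A_ij = A_jk = 1 but A_ik = 0  <=>  x_ij + x_jk - x_ik < 0
    close = [np.flatnonzero(A[i]) for i in range(N)]
    for i in range(N):
        for j in close[i]:
            if j == i:
                continue
            for k in close[j]:
                if k > i and A[i, k] == 0:
                    viol.append((min(i, k), int(j), max(i, k)))
    return sorted(set(viol))


def solve(
    program: IntegerProgram,
    solver: str = "highs",
    time_limit: float | None = None,
    seed: int = 0,
) -> SolveResult:
    """Solve to certified global optimality (gap 0) by branch and cut.

    Deterministic given the backend and seed.  In lazy-transitivity mode the
    program is re-solved with violated transitivity rows appended until the
    incumbent satisfies them all; the final optimum is identical to the
    full-row build.
    """
    if solver != "highs":
        raise ProgramError(f"unknown solver backend {solver!r}")
    del seed  # HiGHS is deterministic; accepted for interface compatibility

    if program.n_vars == 0:  # single-cell grid: nothing to decide
        return SolveResult("optimal", np.zeros(0), float(program.offset), 0.0, "")

    A, lbs, ubs = program.A, program.lb, program.ub
    lazy = program.meta.get("transitivity") == "lazy"
    pairs = program.meta.get("pairs")
    pidx = {p: i for i, p in enumerate(pairs)} if pairs else {}
    n1n2 = program.meta.get("grid_shape", (0, 0))
    N = n1n2[0] * n1n2[1]

    c_min = -program.objective  # milp minimizes
    options: dict = {"mip_rel_gap": 0.0}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)

    log_lines = []
    for iteration in range(1000):
        constraints = LinearConstraint(A, lbs, ubs) if A.shape[0] else ()
        res = milp(
            c=c_min,
            constraints=constraints,
            integrality=np.ones(program.n_vars),
            bounds=Bounds(0, 1),
            options=options,
        )
        if res.status == 2:
            return SolveResult("infeasible", None, float("nan"), float("inf"),
                               res.message)
        if res.status != 0 or res.x is None:
            assignment = None if res.x is None else np.round(res.x)
            obj = float("nan") if res.x is None else float(
                program.objective @ assignment + program.offset
            )
            gap = float(getattr(res, "mip_gap", float("inf")) or float("inf"))
            return SolveResult("limit", assignment, obj, gap, res.message)
        x = np.round(res.x).astype(int)
        if not lazy:
            break
        viol = _violated_transitivity_rows(x, pidx, N)
        log_lines.append(f"lazy round {iteration}: {len(viol)} violated triples")
        if not viol:
            break
        extra_r, extra_c, extra_d = [], [], []
        for t, (i, j, k) in enumerate(viol):
            # x_ij + x_jk - x_ik >= 0  with (i,k) the violated far pair
            for cell_pair, coef in (
                ((min(i, j), max(i, j)), 1.0),
                ((min(j, k), max(j, k)), 1.0),
                ((min(i, k), max(i, k)), -1.0),
            ):
                extra_r.append(t)
                extra_c.append(pidx[cell_pair])
                extra_d.append(coef)
        new_rows = sp.csr_matrix(
            (extra_d, (extra_r, extra_c)), shape=(len(viol), program.n_vars)
        )
        A = sp.vstack([A, new_rows], format="csr")
        lbs = np.concatenate([lbs, np.zeros(len(viol))])
        ubs = np.concatenate([ubs, np.full(len(viol), 2.0)])

    obj = float(program.objective @ x + program.offset)
    return SolveResult("optimal", x, obj, 0.0, "\n".join(log_lines) or res.message)


def decode_direct(result: SolveResult, grid_shape: tuple[int, int]) -> RectangularPartition:
    """Expand the pair-variable solution into X and decode the partition."""
    if result.status != "optimal":
        raise ProgramError(f"cannot decode non-optimal result (status={result.status})")
    n1, n2 = grid_shape
    N = n1 * n2
    _, pairs = _pair_layout(N)
    x = np.zeros((N, N), dtype=np.int8)
    for (a, b), val in zip(pairs, result.assignment):
        x[a, b] = x[b, a] = int(round(val))
    try:
        return x_to_partition(x.reshape(n1, n2, n1, n2)).canonical()
    except PartitionError as exc:  # solver/build inconsistency
        raise ProgramError(f"internal consistency error decoding X: {exc}") from exc


def objective_direct(S, P: RectangularPartition, lam: float) -> float:
    """Exact Eq-style objective <S, 1-X> + lambda <1, X> (diagonal included)."""
    v = _as_similarity_array(S)
    if v.shape[:2] != tuple(P.grid_shape):
        raise ProgramError(
            f"shape mismatch: similarity {v.shape[:2]} vs grid {P.grid_shape}"
        )
    x = partition_to_x(P)
    return float(np.sum(v * (1 - x)) + lam * np.sum(x))


def brute_force_direct(S, lam: float) -> tuple[RectangularPartition, float]:
    """Exhaustive optimum over all rectangular partitions (small grids only)."""
    v = _as_similarity_array(S)
    n1, n2 = v.shape[:2]
    if n1 * n2 > ORACLE_CELL_LIMIT:
        raise ProgramError(
            f"grid {n1}x{n2} exceeds the {ORACLE_CELL_LIMIT}-cell oracle limit"
        )
    best: tuple[RectangularPartition, float] | None = None
    for P in enumerate_rectangular_partitions(n1, n2):
        val = objective_direct(v, P, lam)
        if best is None or val > best[1] + 1e-12:
            best = (P.canonical(), val)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Refinement formulation (one-hot Y given seed W)
# ---------------------------------------------------------------------------

def build_refine_program(W: np.ndarray) -> IntegerProgram:
    """Build the seed-refinement ILP ``max <W, Y>`` from an assignment tensor."""
    W = np.asarray(W)
    if W.ndim != 3:
        raise ProgramError("W must have shape (n1,n2,m)")
    if np.any(W.sum(axis=2) != 1):
        raise ProgramError("W rows must sum to 1 (hard assignment)")
    n1, n2, m = W.shape

    def vid(i: int, j: int, r: int) -> int:
        return (i * n2 + j) * m + r

    nv = n1 * n2 * m
    rows_i: list[int] = []
    cols_i: list[int] = []
    data: list[float] = []
    lbs: list[float] = []
    ubs: list[float] = []

    r_count = 0
    for i in range(n1):  # unique assignment
        for j in range(n2):
            for r in range(m):
                rows_i.append(r_count)
                cols_i.append(vid(i, j, r))
                data.append(1.0)
            lbs.append(1.0)
            ubs.append(1.0)
            r_count += 1
    # interpretability: y_ikr + y_jlr - y_ilr <= 1 for all i!=j, k!=l, r
    for i in range(n1):
        for j in range(n1):
            if i == j:
                continue
            for k in range(n2):
                for l in range(n2):
                    if k == l:
                        continue
                    for r in range(m):
                        rows_i.extend((r_count, r_count, r_count))
                        cols_i.extend((vid(i, k, r), vid(j, l, r), vid(i, l, r)))
                        data.extend((1.0, 1.0, -1.0))
                        lbs.append(-1.0)
                        ubs.append(1.0)
                        r_count += 1

    A = sp.csr_matrix((data, (rows_i, cols_i)), shape=(r_count, nv))
    return IntegerProgram(
        var_names=[f"y_{i}_{j}_{r}" for i in range(n1) for j in range(n2)
                   for r in range(m)],
        A=A,
        lb=np.array(lbs),
        ub=np.array(ubs),
        objective=W.astype(float).reshape(-1),
        offset=0.0,
        meta={"kind": "refine", "grid_shape": (n1, n2), "m": m},
    )


def decode_refine(
    result: SolveResult, grid_shape: tuple[int, int], m: int
) -> RectangularPartition:
    """Decode Y slices into a partition; each used slice must be rectangular."""
    if result.status != "optimal":
        raise ProgramError(f"cannot decode non-optimal result (status={result.status})")
    y = np.round(result.assignment).astype(int).reshape(grid_shape[0], grid_shape[1], m)
    try:
        return y_to_partition(y, require_rectangular=True).canonical()
    except PartitionError as exc:
        raise ProgramError(f"internal consistency error decoding Y: {exc}") from exc


def brute_force_refine(W: np.ndarray) -> tuple[RectangularPartition, float]:
    """Exhaustive optimum of <W, Y> over rectangular partitions with <= m clusters.

    Cluster-to-slice labelling is optimized by maximum-weight matching.
    """
    W = np.asarray(W, dtype=float)
    n1, n2, m = W.shape
    if n1 * n2 > ORACLE_CELL_LIMIT:
        raise ProgramError(
            f"grid {n1}x{n2} exceeds the {ORACLE_CELL_LIMIT}-cell oracle limit"
        )
    best: tuple[RectangularPartition, float] | None = None
    for P in enumerate_rectangular_partitions(n1, n2):
        if P.m > m:
            continue
        match = np.zeros((P.m, m))
        for t, (rows, cols) in enumerate(P.clusters):
            for r in rows:
                for c in cols:
                    match[t] += W[r, c]
        ri, ci = linear_sum_assignment(-match)
        val = float(match[ri, ci].sum())
        if best is None or val > best[1] + 1e-12:
            best = (P.canonical(), val)
    assert best is not None
    return best


def _otsu_cuts(vals: np.ndarray, n_classes: int, bins: int = 256):
    """Histogram-based multi-Otsu: cut indices maximizing between-class variance.

    Returns (class means, class weights) for the best split into
    ``n_classes`` ordered classes (classes may come out empty).
    """
    hist, edges = np.histogram(vals, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = hist / hist.sum()
    P = np.concatenate([[0.0], np.cumsum(p)])
    M = np.concatenate([[0.0], np.cumsum(p * centers)])

    def stats(a, b):  # class over bins [a, b)
        w = P[b] - P[a]
        mu = (M[b] - M[a]) / w if w > 0 else np.nan
        return w, mu

    best = (-1.0, None)
    if n_classes == 2:
        for t in range(1, bins):
            (w0, m0), (w1, m1) = stats(0, t), stats(t, bins)
            if w0 <= 0 or w1 <= 0:
                continue
            score = w0 * w1 * (m1 - m0) ** 2
            if score > best[0]:
                best = (score, ((w0, m0), (w1, m1)))
    else:  # n_classes == 3
        mu_all = M[-1]
        for t1 in range(1, bins - 1):
            for t2 in range(t1 + 1, bins):
                parts = [stats(0, t1), stats(t1, t2), stats(t2, bins)]
                if any(w <= 0 for w, _ in parts):
                    continue
                score = sum(w * (mu - mu_all) ** 2 for w, mu in parts)
                if score > best[0]:
                    best = (score, tuple(parts))
    return best[1]


def suggest_lambda(S) -> float:
    """Data-driven pair penalty from the off-diagonal similarity distribution.

    Within-cluster similarities concentrate near the top of the distribution
    while cross-cluster similarities form one or more lower modes.  A
    three-class Otsu segmentation separates the top (within) mode from the
    nearest cross mode, and ``lambda`` is set to the midpoint of the two
    upper class means — above every cross-cluster mode, below the within
    mode, without consulting any true partition.  When the three-class split
    degenerates, the two-class Otsu midpoint is used instead; intended for
    clearly separated, low-noise similarity structure (otherwise scan
    ``lambda`` explicitly).
    """
    v = _as_similarity_array(S)
    n1, n2 = v.shape[:2]
    N = n1 * n2
    Smat = v.reshape(N, N)
    off = Smat[np.triu_indices(N, k=1)]
    if off.size == 0:
        return 0.5
    if np.ptp(off) < 1e-12:
        return float(off[0])
    three = _otsu_cuts(off, 3)
    if three is not None:
        (_, _), (_, m1), (_, m2) = three
        return float((m1 + m2) / 2.0)
    two = _otsu_cuts(off, 2)
    if two is not None:
        (_, m0), (_, m1) = two
        return float((m0 + m1) / 2.0)
    return float(np.mean(off))


# ---------------------------------------------------------------------------
# LP export
# ---------------------------------------------------------------------------

def export_lp(program: IntegerProgram, path) -> None:
    """Write the program in CPLEX LP text format for external inspection."""
    A = program.A.tocsr()
    with open(path, "w") as fh:
        fh.write("Maximize\n obj:")
        for i, coef in enumerate(program.objective):
            if coef:
                fh.write(f" {coef:+g} {program.var_names[i]}")
        fh.write("\nSubject To\n")
        row = 0
        for r in range(A.shape[0]):
            terms = " ".join(
                f"{A.data[k]:+g} {program.var_names[A.indices[k]]}"
                for k in range(A.indptr[r], A.indptr[r + 1])
            )
            lo, hi = program.lb[r], program.ub[r]
            if lo == hi:
                fh.write(f" c{row}: {terms} = {lo:g}\n")
                row += 1
            else:
                fh.write(f" c{row}: {terms} >= {lo:g}\n")
                row += 1
                fh.write(f" c{row}: {terms} <= {hi:g}\n")
                row += 1
        fh.write("Binary\n")
        for name in program.var_names:
            fh.write(f" {name}\n")
        fh.write("End\n")
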