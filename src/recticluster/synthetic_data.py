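"""Synthetic complete tensors with planted rectangular cluster structure.

Every stage of the pipeline is testable without the original breast-cancer
dataset: a random rectangular partition of the cell-line x ligand grid is
planted, each cluster is assigned a crosstalk mechanism (an ODE model with
fixed parameters), and every grid cell's dose/time/protein curves are that
mechanism's simulated response plus additive truncated-Gaussian noise.  The
default mechanism library uses maximally distinguishable response signatures
(receptor-to-pERK only, receptor-to-pAKT only, balanced dual activation, and
crosstalk variants) so that within-cluster cosine similarity is high and
cross-cluster similarity is substantially lower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_space import ModelSpec, SimulationError, simulate
from .rect_partition import PartitionError, RectangularPartition, validate_partition
from .tensor_core import DataTensor

DEFAULT_TIMES = (0.5, 1.0, 2.0)
DEFAULT_DOSES = (1.0, 0.25)
DEFAULT_PROTEINS = ("pERK", "pAKT")


def _mech(interactions, params, **kw) -> tuple[ModelSpec, dict[str, float]]:
    return ModelSpec(interactions=tuple(interactions), **kw), params


#: Planting library: distinct single- and two-edge mechanisms, ordered so the
#: first three have near-orthogonal or well-separated response signatures.
MECHANISM_LIBRARY: tuple[tuple[ModelSpec, dict[str, float]], ...] = (
    _mech(
        ((("R", "E"), "activation"),),
        {"delta_R": 0.4, "delta_E": 0.6, "k_RE": 4.0},
    ),
    _mech(
        ((("R", "A"), "activation"),),
        {"delta_R": 0.4, "delta_A": 0.6, "k_RA": 4.0},
    ),
    _mech(
        ((("R", "E"), "activation"), (("R", "A"), "activation")),
        {"delta_R": 0.4, "delta_E": 0.6, "delta_A": 0.6, "k_RE": 2.0, "k_RA": 2.0},
    ),
    _mech(
        ((("R", "E"), "activation"), (("E", "A"), "activation")),
        {"delta_R": 0.4, "delta_E": 0.5, "delta_A": 0.5, "k_RE": 5.0, "k_EA": 1.5},
    ),
    _mech(
        ((("R", "A"), "activation"), (("A", "E"), "activation")),
        {"delta_R": 0.4, "delta_E": 0.5, "delta_A": 0.5, "k_RA": 5.0, "k_AE": 1.5},
    ),
    _mech(
        ((("R", "E"), "activation"), (("R", "A"), "activation"),
         (("A", "E"), "inhibition")),
        {"delta_R": 1.2, "delta_E": 0.3, "delta_A": 0.3, "k_RE": 3.0, "k_RA": 1.0,
         "krem_AE": 4.0},
        inhibition_mechanism="removal",
    ),
)


def identifiable_mechanism_pool() -> list[ModelSpec]:
    """Single- and two-edge mass-action models whose parameters all matter.

    Keeps models in which the receptor drives at least one observable, every
    edge's source species can become nonzero (live), and every inhibition
    edge targets a species that is actually produced — the conditions under
    which noise-free data determine every parameter.  Pure-activation models
    are mechanism-independent, so duplicates across inhibition conventions
    are dropped.
    """
    out: list[ModelSpec] = []
    seen = set()
    for mech in ("blocking", "removal"):
        for m in enumerate_models_cached(mech):
            edges = m.edges("activation") + m.edges("inhibition")
            if not 1 <= len(edges) <= 2:
                continue
            if not m.all_edges_live() or m.has_void_edges():
                continue
            produced = {t for (_, t), s in m.interactions if s == "activation"}
            if any(t not in produced for _, t in m.edges("inhibition")):
                continue
            key = (m.interactions,
                   m.inhibition_mechanism if m.edges("inhibition") else "-")
            if key not in seen:
                seen.add(key)
                out.append(m)
    return out


def enumerate_models_cached(mech: str) -> list[ModelSpec]:
    from .model_space import enumerate_models

    return enumerate_models(require_receptor_edge=True, inhibition_mechanism=mech)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: partition, per-cluster mechanisms, noise level."""

    partition: RectangularPartition
    mechanisms: tuple[tuple[ModelSpec, dict[str, float]], ...]
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        problems = validate_partition(self.partition)
        if problems:
            raise PartitionError("; ".join(problems))
        if len(self.mechanisms) < self.partition.m:
            raise PartitionError(
                f"{self.partition.m} clusters but only "
                f"{len(self.mechanisms)} mechanisms"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def sample_rectangular_partition(
    n1: int, n2: int, m: int, seed: int = 0
) -> RectangularPartition:
    """Random rectangular partition with exactly m non-empty clusters.

    Built by repeatedly splitting a uniformly chosen splittable cluster's
    row-set or column-set into two random non-empty parts; the parts need
    not be contiguous, so disconnected rectangles arise naturally.
    """
    if not 1 <= m <= n1 * n2:
        raise PartitionError(f"cannot place m={m} clusters on a {n1}x{n2} grid")
    rng = np.random.default_rng(seed)
    clusters: list[tuple[frozenset[int], frozenset[int]]] = [
        (frozenset(range(n1)), frozenset(range(n2)))
    ]
    while len(clusters) < m:
        splittable = [
            i for i, (rows, cols) in enumerate(clusters)
            if len(rows) > 1 or len(cols) > 1
        ]
        i = int(rng.choice(splittable))
        rows, cols = clusters.pop(i)
        axis_rows = len(rows) > 1 and (len(cols) == 1 or rng.random() < 0.5)
        items = sorted(rows if axis_rows else cols)
        cut = rng.permutation(len(items))
        size_a = int(rng.integers(1, len(items)))
        part_a = frozenset(items[j] for j in cut[:size_a])
        part_b = frozenset(items[j] for j in cut[size_a:])
        if axis_rows:
            clusters += [(part_a, cols), (part_b, cols)]
        else:
            clusters += [(rows, part_a), (rows, part_b)]
    P = RectangularPartition((n1, n2), tuple(clusters)).canonical()
    problems = validate_partition(P)
    if problems:  # construction invariant; should never fire
        raise PartitionError("; ".join(problems))
    return P


def generate_dataset(
    truth: SyntheticTruth,
    doses: tuple[float, ...] = DEFAULT_DOSES,
    times: tuple[float, ...] = DEFAULT_TIMES,
    proteins: tuple[str, ...] = DEFAULT_PROTEINS,
    dose_jitter: float = 0.0,
) -> DataTensor:
    """Simulate the complete cell-line x ligand x dose x time x protein tensor.

    Each grid cell's curves are its cluster mechanism's response; with
    ``dose_jitter`` > 0 every cell additionally gets a log-normal
    multiplicative factor on its dose scales (cell-specific sensitivity).
    Additive Gaussian noise with standard deviation ``truth.noise_sigma`` is
    truncated at zero so the tensor stays non-negative and complete.
    """
    n1, n2 = truth.partition.grid_shape
    rng = np.random.default_rng(truth.seed)
    g = truth.partition.membership_grid()

    responses = {}
    values = np.empty((n1, n2, len(doses), len(times), len(proteins)))
    for r in range(n1):
        for c in range(n2):
            k = int(g[r, c])
            spec, params = truth.mechanisms[k]
            factor = (
                float(np.exp(rng.normal(0.0, dose_jitter))) if dose_jitter else 1.0
            )
            key = (k, factor)
            if key not in responses:
                try:
                    traj = simulate(
                        spec, params, times,
                        tuple(d * factor for d in doses),
                    )
                except SimulationError as exc:
                    raise SimulationError(
                        f"mechanism {spec.label()} failed for cluster {k}: {exc}"
                    ) from exc
                responses[key] = traj.values  # (n_dose, n_time, 2)
            cell = responses[key].copy()
            if truth.noise_sigma > 0:
                cell = np.maximum(
                    cell + rng.normal(0.0, truth.noise_sigma, size=cell.shape), 0.0
                )
            values[r, c] = cell

    return DataTensor(
        values=values,
        axes=(
            ("cell_line", tuple(f"C{i + 1:02d}" for i in range(n1))),
            ("ligand", tuple(f"L{j + 1:02d}" for j in range(n2))),
            ("dose", tuple(str(d) for d in doses)),
            ("time", tuple(str(t) for t in times)),
            ("protein", tuple(proteins)),
        ),
    )


def planted_instance(
    n1: int,
    n2: int,
    m: int,
    sigma: float,
    seed: int,
    dose_jitter: float = 0.0,
) -> tuple[DataTensor, SyntheticTruth]:
    """Convenience wrapper: sample a partition, attach mechanisms, simulate."""
    if m > len(MECHANISM_LIBRARY):
        raise PartitionError(
            f"default mechanism library has {len(MECHANISM_LIBRARY)} entries; "
            f"m={m} needs a custom mechanism list"
        )
    P = sample_rectangular_partition(n1, n2, m, seed)
    truth = SyntheticTruth(
        partition=P,
        mechanisms=MECHANISM_LIBRARY[:m],
        noise_sigma=sigma,
        seed=seed,
    )
    return generate_dataset(truth, dose_jitter=dose_jitter), truth
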