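"""End-to-end orchestration: load -> similarity -> cluster -> fit -> report.

A :class:`RunConfig` fully determines a run; every output file is listed in a
manifest with a content hash so that re-running a deterministic configuration
reproduces the outputs bit-exactly.  Stage failures propagate with the stage
name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

from . import ilp_engine, initial_clustering, model_fit, model_space, tensor_core
from .rect_partition import (
    RectangularPartition,
    partition_from_frame,
    partition_to_frame,
    partition_to_json,
)

logger = logging.getLogger("recticluster")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class RunConfig:
    data_path: str
    out_dir: str
    axis_names: tuple[str, ...] = ("cell_line", "ligand", "dose", "time", "protein")
    d: int = 2
    normalization: str = "unit-l2"
    pathway: str = "direct"  # direct | refine
    lam: float | None = None  # None: Otsu-style data-driven choice
    seed_method: str = "agglomerative-average"
    m: int = 3
    init_partition_path: str | None = None
    solver: str = "highs"
    time_limit: float | None = None
    seed: int = 0
    allow_gap: bool = False
    fit_models: bool = False
    fit_top: int = 4
    fit_rounds: int = 6
    fit_samples: int = 100
    plot: bool = True


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as exc:
                raise StageError(f"{name}: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def plot_partition(P: RectangularPartition, path, row_labels=None, col_labels=None):
    """Cluster-coloured n1 x n2 grid image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = P.membership_grid()
    n1, n2 = P.grid_shape
    fig, ax = plt.subplots(figsize=(max(3, n2 * 0.5), max(2, n1 * 0.4)))
    ax.imshow(g, cmap="tab20", aspect="auto", interpolation="nearest")
    ax.set_xticks(range(n2))
    ax.set_yticks(range(n1))
    ax.set_xticklabels(col_labels or range(n2), rotation=90, fontsize=7)
    ax.set_yticklabels(row_labels or range(n1), fontsize=7)
    ax.set_xlabel("ligand")
    ax.set_ylabel("cell line")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _default_fit_pool(n_points: int) -> list[model_space.ModelSpec]:
    """Single- and two-edge candidates from the full pool, filtered for AICc."""
    pool = [
        m for m in model_space.enumerate_models(require_receptor_edge=True)
        if len(m.edges("activation")) + len(m.edges("inhibition")) <= 2
        and not m.has_void_edges()
    ]
    return model_space.identifiability_filter(pool, (n_points, 1, 1))


def run(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    Z = _stage("load_long_table")(tensor_core.load_long_table)(
        config.data_path, config.axis_names
    )
    S_mat, S = _stage("similarity")(tensor_core.similarity_from_tensor)(
        Z, config.d, config.normalization
    )
    sim_path = out / "similarity.csv"
    tensor_core.save_similarity_csv(S_mat, sim_path)

    grid_shape = Z.shape[: config.d]
    lam = config.lam
    certified = True
    if config.pathway == "direct":
        if lam is None:
            lam = ilp_engine.suggest_lambda(S)
        program = _stage("build_direct")(ilp_engine.build_direct_program)(S, lam)
        result = _stage("solve")(ilp_engine.solve)(
            program, config.solver, config.time_limit, config.seed
        )
        certified = result.status == "optimal"
        if not certified and not config.allow_gap:
            raise StageError(
                f"solve: non-certified solution (status={result.status}, "
                f"gap={result.gap}); pass allow_gap to accept"
            )
        P = _stage("decode")(ilp_engine.decode_direct)(result, grid_shape)
        objective = result.objective_value
    elif config.pathway == "refine":
        if config.init_partition_path:
            import pandas as pd

            P0, _, _ = partition_from_frame(pd.read_csv(config.init_partition_path))
            from .rect_partition import partition_to_y

            W = partition_to_y(P0, P0.m)
        else:
            W = _stage("seed_clustering")(initial_clustering.cluster_flat)(
                S_mat, grid_shape, config.m, config.seed_method, config.seed
            )
        program = _stage("build_refine")(ilp_engine.build_refine_program)(W)
        result = _stage("solve")(ilp_engine.solve)(
            program, config.solver, config.time_limit, config.seed
        )
        certified = result.status == "optimal"
        if not certified and not config.allow_gap:
            raise StageError(
                f"solve: non-certified solution (status={result.status})"
            )
        P = _stage("decode")(ilp_engine.decode_refine)(
            result, grid_shape, W.shape[2]
        )
        objective = result.objective_value
    else:
        raise StageError(f"config: unknown pathway {config.pathway!r}")

    row_labels = Z.labels(Z.axis_names[0])
    col_labels = Z.labels(Z.axis_names[1])
    part_path = out / "partition.json"
    part_path.write_text(partition_to_json(P, row_labels, col_labels))
    csv_path = out / "partition.csv"
    partition_to_frame(P, row_labels, col_labels).to_csv(csv_path, index=False)

    n2 = grid_shape[1]
    het = {}
    for k in range(P.m):
        cells = sorted(r * n2 + c for r, c in P.cells(k))
        if len(cells) >= 2:
            het[str(k)] = tensor_core.heterogeneity_score(S_mat, cells)

    files = [sim_path, part_path, csv_path]
    if config.plot:
        plot_path = out / "partition.png"
        _stage("plot")(plot_partition)(P, plot_path, row_labels, col_labels)
        files.append(plot_path)

    ranking = None
    if config.fit_models:
        pool = _default_fit_pool(12)
        opts = model_fit.FitOptions(
            rounds=config.fit_rounds, samples=config.fit_samples, seed=config.seed
        )
        ranking = {}
        for k in range(P.m):
            data = model_fit.mean_response(Z, P, k)
            fits = []
            for spec in pool:
                try:
                    fits.append(model_fit.fit_model(spec, data, opts))
                except model_fit.FitError:
                    continue
            ranking[str(k)] = model_fit.rank_models(fits, top=config.fit_top)
        rank_path = out / "model_ranking.json"
        rank_path.write_text(json.dumps(ranking, indent=2))
        files.append(rank_path)

    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "seed": config.seed,
        "pathway": config.pathway,
        "lambda": lam,
        "objective": objective,
        "certified": certified,
        "n_clusters": P.m,
        "heterogeneity": het,
        "solver_status": result.status,
        "files": {f.name: _hash(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
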