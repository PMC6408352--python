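"""Fitting candidate ODE models to cluster-mean responses and AICc ranking.

Each rectangular cluster's experiments are averaged into a single
dose x time x observable response (n = 12 points by default: two doses,
three time points, pERK and pAKT).  Every candidate model is fitted by
squeeze-and-breathe Monte-Carlo search — iterated rounds of log-uniform
parameter sampling, elite selection and sampling-domain contraction around
the elites, with a periodic re-expansion to escape local minima and a final
local polish — and scored with the small-sample-corrected Akaike information
criterion (Gaussian-likelihood form with the error variance profiled out):

    AICc = n ln(RSS/n) + 2k + 2k(k+1) / (n - k - 1).

Lower is better; the correction term penalizes parameter-rich models hard
when n is as small as 12.  The search is deterministic given its seed and
returns the best parameters found (global optimality is not claimed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .model_space import ModelSpec, SimulationError, simulate
from .rect_partition import RectangularPartition
from .tensor_core import DataTensor

RSS_FLOOR = 1e-12  # guards log(0) for exact fits


class FitError(RuntimeError):
    """Raised when a model cannot be fitted to the data at all."""


@dataclass(frozen=True)
class ClusterResponse:
    """Mean normalized response of one cluster (dose x time x observable)."""

    times: tuple[float, ...]
    dose_scales: tuple[float, ...]
    values: np.ndarray  # (n_doses, n_times, 2) for (pERK, pAKT)
    observables: tuple[str, ...] = ("pERK", "pAKT")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        expected = (len(self.dose_scales), len(self.times), len(self.observables))
        if v.shape != expected:
            raise FitError(f"response shape {v.shape}, expected {expected}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise FitError("response values must be finite and non-negative")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class FitOptions:
    """Squeeze-and-breathe hyperparameters (artifact defaults)."""

    bounds: tuple[float, float] = (1e-3, 1e3)
    rounds: int = 10
    samples: int = 200
    elite_frac: float = 0.1
    contraction: float = 0.5
    breathe_round: int | None = None  # default: midway through the rounds
    polish: bool = True
    n_polish: int = 3  # distinct elites refined by local least squares
    polish_per_round: bool = True  # also polish each round's best (pre-squeeze
    # rounds explore different basins, guarding against mirror-basin traps)
    initial: str = "zero"  # "zero" | "first-observation" for E(0), A(0)
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9


@dataclass(frozen=True)
class FitResult:
    model: ModelSpec
    params: dict[str, float]
    rss: float
    k: int
    aicc: float
    n_evals: int
    seed: int


def mean_response(
    Z: DataTensor,
    P: RectangularPartition,
    cluster_id: int,
    dose_scales: Sequence[float] | None = None,
) -> ClusterResponse:
    """Arithmetic mean over the cluster's (cell line, ligand) grid cells.

    Assumes the canonical axis order (cell_line, ligand, dose, time,
    protein).  Dose and time labels are parsed as numbers when possible;
    otherwise doses default to (1.0, 0.25) (high/low) and times to 1-based
    indices.
    """
    if Z.order != 5:
        raise FitError("expected an order-5 (cells x ligands x dose x time x "
                       "protein) tensor")
    rows, cols = P.clusters[cluster_id]
    if not rows or not cols:
        raise FitError(f"cluster {cluster_id} is empty")
    block = Z.values[np.ix_(sorted(rows), sorted(cols))]
    mean = block.mean(axis=(0, 1))  # (n_dose, n_time, n_protein)

    def _numeric(labels, fallback):
        try:
            return tuple(float(x) for x in labels)
        except ValueError:
            return fallback

    dose_labels = Z.labels(Z.axis_names[2])
    time_labels = Z.labels(Z.axis_names[3])
    if dose_scales is None:
        dose_scales = _numeric(dose_labels, (1.0, 0.25)[: len(dose_labels)])
    times = _numeric(time_labels, tuple(range(1, len(time_labels) + 1)))
    return ClusterResponse(
        times=times,
        dose_scales=tuple(dose_scales),
        values=mean,
        observables=Z.labels(Z.axis_names[4]),
    )


def aicc_score(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected AIC from a Gaussian residual likelihood."""
    if n - k - 1 < 1:
        raise FitError(f"AICc undefined: n-k-1 = {n - k - 1} < 1 (n={n}, k={k})")
    if rss < 0:
        raise FitError("negative residual sum of squares")
    return float(
        n * math.log(max(rss, RSS_FLOOR) / n)
        + 2 * k
        + 2 * k * (k + 1) / (n - k - 1)
    )


def _residuals(model, theta, names, data: ClusterResponse, options):
    params = dict(zip(names, theta))
    if options.initial == "first-observation":
        init = data.values[:, 0, :]
    else:  # zero: unphosphorylated readouts at stimulation onset
        init = np.zeros((len(data.dose_scales), 2))
    try:
        traj = simulate(
            model, params, data.times, data.dose_scales,
            initial=init, rtol=options.rtol, atol=options.atol,
        )
    except SimulationError:
        return None
    return (traj.values - data.values).ravel()


def _loss(model, theta, names, data: ClusterResponse, options) -> float:
    res = _residuals(model, theta, names, data, options)
    return float("inf") if res is None else float(res @ res)


def fit_model(
    model: ModelSpec,
    data: ClusterResponse,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Squeeze-and-breathe parameter search minimizing the residual sum of squares."""
    names = model.parameter_names()
    k = len(names)
    if data.n - k - 1 < 1:
        raise FitError(
            f"model has k={k} parameters for n={data.n} points; "
            "apply the identifiability filter first"
        )
    if k == 0:
        rss = _loss(model, np.zeros(0), names, data, options)
        return FitResult(model, {}, rss, 0, aicc_score(rss, data.n, 0), 1,
                         options.seed)

    rng = np.random.default_rng(options.seed)
    lo0, hi0 = math.log10(options.bounds[0]), math.log10(options.bounds[1])
    lo = np.full(k, lo0)
    hi = np.full(k, hi0)
    n_elite = max(1, int(round(options.elite_frac * options.samples)))
    breathe_at = (
        options.breathe_round
        if options.breathe_round is not None
        else options.rounds // 2
    )

    best_theta: np.ndarray | None = None
    best_loss = float("inf")
    n_evals = 0
    archive: list[tuple[float, np.ndarray]] = []  # elite pool for polish starts
    round_bests: list[np.ndarray] = []
    for rnd in range(options.rounds):
        if rnd == breathe_at and rnd > 0:  # breathe: re-expand the domain
            lo, hi = np.full(k, lo0), np.full(k, hi0)
        logs = rng.uniform(lo, hi, size=(options.samples, k))
        if best_theta is not None:  # carry the incumbent into every round
            logs[0] = np.log10(best_theta)
        losses = np.array([
            _loss(model, 10.0 ** row, names, data, options) for row in logs
        ])
        n_evals += options.samples
        order = np.argsort(losses, kind="stable")
        elites = logs[order[:n_elite]]
        for idx in order[:n_elite]:
            if np.isfinite(losses[idx]):
                archive.append((float(losses[idx]), logs[idx].copy()))
        if np.isfinite(losses[order[0]]):
            round_bests.append(logs[order[0]].copy())
        if losses[order[0]] < best_loss:
            best_loss = float(losses[order[0]])
            best_theta = 10.0 ** logs[order[0]]
        if not np.isfinite(losses[order[0]]):
            continue
        # squeeze: contract the box around the elite cloud
        center = elites.mean(axis=0)
        half = (hi - lo) / 2.0 * options.contraction
        lo = np.clip(center - half, lo0, hi0)
        hi = np.clip(center + half, lo0, hi0)

    if best_theta is None or not np.isfinite(best_loss):
        raise FitError(f"model unfittable on data: {model.label()}")

    if options.polish:
        # local least squares in log space from the best few distinct elites
        archive.sort(key=lambda t: t[0])
        starts, seen = [], set()

        def add_start(logtheta) -> None:
            key = tuple(np.round(logtheta, 1))
            if key not in seen:
                seen.add(key)
                starts.append(logtheta)

        for _, logtheta in archive:
            if len(starts) >= options.n_polish:
                break
            add_start(logtheta)
        if options.polish_per_round:
            for logtheta in round_bests:
                add_start(logtheta)
        # linear compartment cascades are nearly symmetric under exchange of
        # decay rates (e^{-at} - e^{-bt} is symmetric in a, b); probe the
        # mirror basins by polishing decay-permuted copies of the best start
        delta_idx = [i for i, nm in enumerate(names) if nm.startswith("delta_")]
        if len(delta_idx) >= 2 and archive:
            base = archive[0][1]
            for perm in itertools.permutations(delta_idx):
                if list(perm) == delta_idx:
                    continue
                swapped = base.copy()
                swapped[delta_idx] = base[list(perm)]
                add_start(swapped)

        big = 1e6  # finite surrogate for failed integrations inside least_squares
        n_res = data.n

        def resid_log(u):
            r = _residuals(model, 10.0 ** u, names, data, options)
            return np.full(n_res, big) if r is None else r

        for u0 in starts:
            try:
                res = least_squares(
                    resid_log, u0, method="trf",
                    bounds=(np.full(k, lo0), np.full(k, hi0)),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=200 * k,
                )
            except Exception:
                continue
            n_evals += res.nfev
            cand = 10.0 ** res.x
            cand_loss = _loss(model, cand, names, data, options)
            n_evals += 1
            if np.isfinite(cand_loss) and cand_loss < best_loss:
                best_loss = float(cand_loss)
                best_theta = cand

    return FitResult(
        model=model,
        params=dict(zip(names, (float(t) for t in best_theta))),
        rss=float(best_loss),
        k=k,
        aicc=aicc_score(float(best_loss), data.n, k),
        n_evals=n_evals,
        seed=options.seed,
    )


def rank_models(fits: Sequence[FitResult], top: int | None = None) -> list[dict]:
    """Ascending-AICc ranking with delta-AICc from the best model.

    Ties are broken by smaller parameter count, then by the canonical model
    serialization, so the report is deterministic.
    """
    if not fits:
        raise FitError("no fits to rank")
    ordered = sorted(fits, key=lambda f: (f.aicc, f.k, f.model.to_json()))
    best = ordered[0].aicc
    report = [
        {
            "rank": i + 1,
            "model": f.model.label(),
            "model_json": f.model.to_json(),
            "k": f.k,
            "rss": f.rss,
            "aicc": f.aicc,
            "delta_aicc": f.aicc - best,
            "params": f.params,
        }
        for i, f in enumerate(ordered)
    ]
    return report[:top] if top else report
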