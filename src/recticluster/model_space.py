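"""Candidate 3-species receptor/pERK/pAKT crosstalk ODE models.

Each candidate model assigns one of {activation, inhibition, none} to the six
ordered species pairs R->E, R->A, E->A, A->E, E->R, A->R, where R is the
(latent) ligand-bound receptor, E is phosphorylated ERK and A is
phosphorylated AKT.  The default enumeration of all sign patterns gives
3^6 = 729 candidate network models; kinetic regime (mass action vs
Michaelis-Menten) and inhibition mechanism (blocking/sequestration vs
removal/degradation) are uniform, config-switchable conventions.  This
combinatorial scheme is a documented reconstruction: the generator is fully
config-driven so any externally derived model list can be supplied instead.

Dynamics conventions (all config-free, documented in the methods note):

* receptor: ``dR/dt = -delta_R * R`` plus any activation influx, with
  ``R(0) = dose_scale`` and capacity ``R_tot = dose_scale``;
* activation of target T by source U: mass action ``k * U * (T_tot - T)`` or
  Michaelis-Menten ``V * U * (T_tot - T) / (K + T_tot - T)``, with
  ``T_tot = 1`` for E and A (normalized data);
* blocking inhibition of T by I: all activation influx into T is multiplied
  by ``1 / (1 + I / K_I)`` (structurally void if T has no activation influx);
* removal inhibition of T by I: extra term ``-k_rem * I * T``;
* first-order decay ``-delta_T * T`` for every species with at least one
  incoming edge (and always for R).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

SPECIES = ("R", "E", "A")
OBSERVABLES = ("E", "A")
PAIRS: tuple[tuple[str, str], ...] = (
    ("R", "E"), ("R", "A"), ("E", "A"), ("A", "E"), ("E", "R"), ("A", "R"),
)
SIGNS = ("activation", "inhibition", "none")


class ModelError(ValueError):
    """Raised for malformed model specifications."""


class SimulationError(RuntimeError):
    """Raised when numerical integration fails or produces invalid output."""


@dataclass(frozen=True)
class ModelSpec:
    """A signed-interaction crosstalk model with fixed kinetic conventions."""

    interactions: tuple[tuple[tuple[str, str], str], ...]
    kinetics: str = "mass_action"
    inhibition_mechanism: str = "blocking"

    def __post_init__(self) -> None:
        inter = dict(self.interactions)
        for pair in inter:
            if pair not in PAIRS:
                raise ModelError(f"unknown species pair {pair}")
        for pair in PAIRS:
            inter.setdefault(pair, "none")
        for pair, sign in inter.items():
            if sign not in SIGNS:
                raise ModelError(f"invalid sign {sign!r} for {pair}")
        if self.kinetics not in ("mass_action", "michaelis_menten"):
            raise ModelError(f"invalid kinetics {self.kinetics!r}")
        if self.inhibition_mechanism not in ("blocking", "removal"):
            raise ModelError(
                f"invalid inhibition mechanism {self.inhibition_mechanism!r}"
            )
        object.__setattr__(
            self, "interactions", tuple((p, inter[p]) for p in PAIRS)
        )

    def sign(self, source: str, target: str) -> str:
        return dict(self.interactions)[(source, target)]

    def edges(self, kind: str) -> list[tuple[str, str]]:
        return [p for p, s in self.interactions if s == kind]

    def has_receptor_edge(self) -> bool:
        """The receptor phosphorylates ERK and/or AKT."""
        return self.sign("R", "E") != "none" or self.sign("R", "A") != "none"

    def _activation_influx(self, target: str) -> list[str]:
        return [u for (u, t), s in self.interactions if t == target
                and s == "activation"]

    def all_edges_live(self) -> bool:
        """True if every non-none edge has a source that can become nonzero.

        Species are "live" when reachable from the receptor through
        activation edges (R itself is live via the dose).  An edge whose
        source stays identically zero contributes nothing to the dynamics,
        so its parameters cannot be identified from any data.
        """
        live = {"R"}
        changed = True
        while changed:
            changed = False
            for (u, t), s in self.interactions:
                if s == "activation" and u in live and t not in live:
                    live.add(t)
                    changed = True
        return all(u in live for (u, _), s in self.interactions if s != "none")

    def has_void_edges(self) -> bool:
        """True if some blocking-inhibition edge targets a species with no
        activation influx: such an edge contributes no term and no parameter,
        making the model observationally identical to the one without it."""
        if self.inhibition_mechanism != "blocking":
            return False
        return any(
            s == "inhibition" and not self._activation_influx(t)
            for (_, t), s in self.interactions
        )

    def parameter_names(self) -> tuple[str, ...]:
        """Deterministic parameter list.

        delta_R always; delta_T for T in {E, A} with any incoming edge;
        one rate per mass-action activation edge (two for Michaelis-Menten);
        one K_I per blocking edge whose target has activation influx; one
        removal rate per removal edge.  Edges that cannot affect the dynamics
        under these conventions contribute no parameters.
        """
        names = ["delta_R"]
        for t in OBSERVABLES:
            if any(tt == t and s != "none" for (_, tt), s in self.interactions):
                names.append(f"delta_{t}")
        for (u, t), s in self.interactions:
            if s == "activation":
                if self.kinetics == "mass_action":
                    names.append(f"k_{u}{t}")
                else:
                    names.extend((f"V_{u}{t}", f"K_{u}{t}"))
            elif s == "inhibition":
                if self.inhibition_mechanism == "removal":
                    names.append(f"krem_{u}{t}")
                elif self._activation_influx(t):
                    names.append(f"KI_{u}{t}")
        return tuple(names)

    @property
    def k(self) -> int:
        return len(self.parameter_names())

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "interactions": {f"{u}->{t}": s for (u, t), s in self.interactions},
                "kinetics": self.kinetics,
                "inhibition_mechanism": self.inhibition_mechanism,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        obj = json.loads(text)
        inter = tuple(
            (tuple(key.split("->")), sign)
            for key, sign in obj["interactions"].items()
        )
        return cls(
            interactions=inter,
            kinetics=obj["kinetics"],
            inhibition_mechanism=obj["inhibition_mechanism"],
        )

    def label(self) -> str:
        parts = []
        glyph = {"activation": "+", "inhibition": "-"}
        for (u, t), s in self.interactions:
            if s != "none":
                parts.append(f"{u}{glyph[s]}{t}")
        return ",".join(parts) if parts else "null"


@dataclass(frozen=True)
class Trajectory:
    """Simulated observable time courses per dose."""

    times: tuple[float, ...]
    dose_scales: tuple[float, ...]
    values: np.ndarray  # (n_doses, n_times, 2) for (E, A)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.dose_scales), len(self.times), len(OBSERVABLES)):
            raise ModelError(f"trajectory shape {v.shape} inconsistent")


def enumerate_models(
    pairs: Sequence[tuple[str, str]] = PAIRS,
    signs: Sequence[str] = SIGNS,
    kinetics: str = "mass_action",
    inhibition_mechanism: str = "blocking",
    require_receptor_edge: bool = False,
) -> list[ModelSpec]:
    """Enumerate the candidate pool (default: 3 signs ^ 6 pairs = 729 models).

    ``require_receptor_edge`` drops models in which the receptor
    phosphorylates neither ERK nor AKT.
    """
    pool = []
    for combo in itertools.product(signs, repeat=len(pairs)):
        spec = ModelSpec(
            interactions=tuple(zip(tuple(pairs), combo)),
            kinetics=kinetics,
            inhibition_mechanism=inhibition_mechanism,
        )
        if require_receptor_edge and not spec.has_receptor_edge():
            continue
        pool.append(spec)
    return pool


def identifiability_filter(
    models: Iterable[ModelSpec],
    data_shape: tuple[int, int, int],
    whitelist: Sequence[ModelSpec] | None = None,
    sensitivity_screen: bool = False,
    reference_point: float = 1.0,
    times: Sequence[float] = (0.5, 1.0, 2.0),
    dose_scales: Sequence[float] = (1.0, 0.25),
) -> list[ModelSpec]:
    """Practical surrogate for a structural-identifiability screen.

    Retains models whose parameter count k satisfies ``n - k - 1 >= 1``
    (AICc well defined for n = prod(data_shape) data points) and, optionally,
    whose output sensitivity matrix at a reference parameter point has full
    column rank.  A user-supplied ``whitelist`` short-circuits both screens
    so an externally derived model list can be reproduced exactly.
    """
    if whitelist is not None:
        wanted = {m.to_json() for m in whitelist}
        return [m for m in models if m.to_json() in wanted]
    n = int(np.prod(data_shape))
    kept = []
    for m in models:
        if n - m.k - 1 < 1:
            continue
        if sensitivity_screen and not _full_sensitivity_rank(
            m, reference_point, times, dose_scales
        ):
            continue
        kept.append(m)
    return kept


def _full_sensitivity_rank(model, ref, times, dose_scales) -> bool:
    names = model.parameter_names()
    base = {p: ref for p in names}
    try:
        y0 = simulate(model, base, times, dose_scales).values.ravel()
    except SimulationError:
        return False
    cols = []
    for p in names:
        pert = dict(base)
        pert[p] = ref * 1.05
        try:
            y1 = simulate(model, pert, times, dose_scales).values.ravel()
        except SimulationError:
            return False
        cols.append((y1 - y0) / (0.05 * ref))
    J = np.column_stack(cols)
    return np.linalg.matrix_rank(J, tol=1e-9) == len(names)


def _build_rhs(model: ModelSpec, params: Mapping[str, float], r_tot: float):
    """Compile the right-hand side into a term list closure."""
    idx = {s: i for i, s in enumerate(SPECIES)}
    totals = np.array([r_tot, 1.0, 1.0])
    deltas = np.zeros(3)
    for s in SPECIES:
        deltas[idx[s]] = params.get(f"delta_{s}", 0.0)

    # per-target lists of (source_idx, kind, p1, p2)
    act: list[list[tuple[int, float, float]]] = [[], [], []]
    block: list[list[tuple[int, float]]] = [[], [], []]
    remv: list[list[tuple[int, float]]] = [[], [], []]
    mm = model.kinetics == "michaelis_menten"
    for (u, t), s in model.interactions:
        ui, ti = idx[u], idx[t]
        if s == "activation":
            if mm:
                act[ti].append((ui, params[f"V_{u}{t}"], params[f"K_{u}{t}"]))
            else:
                act[ti].append((ui, params[f"k_{u}{t}"], np.nan))
        elif s == "inhibition":
            if model.inhibition_mechanism == "removal":
                remv[ti].append((ui, params[f"krem_{u}{t}"]))
            elif f"KI_{u}{t}" in params:  # void when target has no activation influx
                block[ti].append((ui, params[f"KI_{u}{t}"]))

    def rhs(t, s):
        d = -deltas * s
        for ti in range(3):
            free = totals[ti] - s[ti]
            influx = 0.0
            for ui, p1, p2 in act[ti]:
                if mm:
                    influx += p1 * s[ui] * free / (p2 + free)
                else:
                    influx += p1 * s[ui] * free
            if influx and block[ti]:
                for ui, ki in block[ti]:
                    influx /= 1.0 + s[ui] / ki
            d[ti] += influx
            for ui, kr in remv[ti]:
                d[ti] -= kr * s[ui] * s[ti]
        return d

    return rhs


def simulate(
    model: ModelSpec,
    params: Mapping[str, float],
    times: Sequence[float],
    dose_scales: Sequence[float],
    initial: tuple[float, ...] | np.ndarray = (0.0, 0.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model and return E, A at the requested times per dose.

    ``initial`` gives E(0), A(0), either shared across doses (length 2) or
    per dose (shape ``(n_doses, 2)``); R(0) equals the dose scale.  Blow-ups
    and integration failures raise :class:`SimulationError` (mapped to
    infinite loss by the fitting layer); genuinely negative output is an
    error, never silently clipped.
    """
    times = tuple(float(t) for t in times)
    if any(b <= a for a, b in zip(times, times[1:])) or times[0] < 0:
        raise ModelError("times must be non-negative and strictly increasing")
    init = np.asarray(initial, dtype=float)
    if init.ndim == 1:
        init = np.tile(init, (len(dose_scales), 1))
    out = np.empty((len(dose_scales), len(times), 2))
    missing = [p for p in model.parameter_names() if p not in params]
    if missing:
        raise ModelError(f"missing parameters {missing}")
    for di, scale in enumerate(dose_scales):
        rhs = _build_rhs(model, params, float(scale))
        y0 = np.array([float(scale), init[di, 0], init[di, 1]])
        sol = solve_ivp(
            rhs, (0.0, times[-1]), y0, method="LSODA", t_eval=times,
            rtol=rtol, atol=atol,
        )
        if not sol.success or sol.y.shape[1] != len(times):
            raise SimulationError(
                f"integration failed for params {dict(params)}: {sol.message}"
            )
        ea = sol.y[1:3].T  # (n_times, 2)
        if not np.all(np.isfinite(ea)):
            raise SimulationError(f"non-finite trajectory for params {dict(params)}")
        if np.min(ea) < -1e-6:
            raise SimulationError(
                f"negative trajectory (min {np.min(ea):.3g}) for params "
                f"{dict(params)}"
            )
        out[di] = np.maximum(ea, 0.0)  # floor solver-tolerance jitter only
    return Trajectory(times=times, dose_scales=tuple(float(s) for s in dose_scales),
                      values=out)


def pool_to_jsonl(models: Sequence[ModelSpec], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(m.to_json() + "\n")


def pool_from_jsonl(path) -> list[ModelSpec]:
    with open(path) as fh:
        return [ModelSpec.from_json(line) for line in fh if line.strip()]
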