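"""Linear and quadratic programming services over metabolic models.

Flux Balance Analysis (FBA) maximizes the objective reaction's flux subject
to steady-state mass balance ``S v = 0`` and flux bounds; Flux Variability
Analysis (FVA) computes per-reaction flux ranges at a fraction of that
optimum; MoMA (Minimization of Metabolic Adjustment) predicts post-knockout
fluxes as the closest feasible point to a wild-type distribution.

The LP engine is scipy's HiGHS interface; the quadratic MoMA variant runs on
OSQP. Both are deterministic for a fixed model, which downstream flux-ratio
logic relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicModel, Reaction

__all__ = [
    "FluxDistribution",
    "FvaResult",
    "MetabolicTask",
    "InfeasibleModelError",
    "DEFAULT_TOL",
    "fba",
    "fva",
    "find_blocked_reactions",
    "remove_dead_ends",
    "leak_test",
    "moma",
    "check_metabolic_task",
    "load_tasks",
]

#: "Zero flux" tolerance; typical LP feasibility tolerance.
DEFAULT_TOL = 1e-6


class InfeasibleModelError(RuntimeError):
    """The LP/QP had no feasible solution; carries the solver status."""

    def __init__(self, message: str, status: str = "infeasible") -> None:
        super().__init__(f"{message} (solver status: {status})")
        self.status = status


@dataclass
class FluxDistribution:
    """A steady-state flux vector (mmol/gDW/hr) plus its objective value."""

    fluxes: Dict[str, float]
    objective_value: float

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def get(self, rxn_id: str, default: float = 0.0) -> float:
        return self.fluxes.get(rxn_id, default)


@dataclass
class FvaResult:
    """Per-reaction attainable flux range at a stated objective fraction."""

    ranges: Dict[str, Tuple[float, float]]
    objective_fraction: float

    def minimum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][0]

    def maximum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][1]


@dataclass
class MetabolicTask:
    """Feasibility check: can the model make ``outputs`` from ``inputs`` alone?"""

    id: str
    inputs: Dict[str, float]
    outputs: Set[str]
    expected: str = "pass"  # pass | fail


# ---------------------------------------------------------------------------
# matrix extraction and the LP port
# ---------------------------------------------------------------------------

def _matrices(model: MetabolicModel):
    S = model.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return S, lb, ub


def _objective_vector(model: MetabolicModel) -> np.ndarray:
    c = np.zeros(len(model.reactions))
    if not model.objective_reaction:
        raise InfeasibleModelError("model has no objective reaction", "no-objective")
    c[model._rxn_index[model.objective_reaction]] = 1.0
    return c


def _solve_lp(
    c_min: np.ndarray,
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
) -> np.ndarray:
    """min c_min . v  s.t.  S v = 0, A_ub v <= b_ub, lb <= v <= ub."""

    res = linprog(
        c_min,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if not res.success:
        raise InfeasibleModelError("linear program failed", res.message.strip())
    return res.x


# ---------------------------------------------------------------------------
# FBA / FVA / blocked reactions
# ---------------------------------------------------------------------------

def fba(model: MetabolicModel) -> FluxDistribution:
    """Maximize the objective reaction's flux; returns one optimal vertex."""

    S, lb, ub = _matrices(model)
    c = _objective_vector(model)
    v = _solve_lp(-c, S, lb, ub)
    return FluxDistribution(
        fluxes={r.id: float(x) for r, x in zip(model.reactions, v)},
        objective_value=float(c @ v),
    )


def fva(
    model: MetabolicModel,
    objective_fraction: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
) -> FvaResult:
    """Per-reaction min/max flux subject to objective >= fraction * optimum."""

    if not 0.0 <= objective_fraction <= 1.0:
        raise ValueError("objective_fraction must be in [0, 1]")
    S, lb, ub = _matrices(model)
    c = _objective_vector(model)
    opt = fba(model).objective_value
    A_ub = -c[None, :]
    b_ub = np.array([-objective_fraction * opt])
    targets = list(reactions) if reactions is not None else model.reaction_ids
    ranges: Dict[str, Tuple[float, float]] = {}
    for rxn_id in targets:
        j = model._rxn_index[rxn_id]
        e = np.zeros(len(model.reactions))
        e[j] = 1.0
        vmin = float(_solve_lp(e, S, lb, ub, A_ub, b_ub)[j])
        vmax = float(-(-_solve_lp(-e, S, lb, ub, A_ub, b_ub)[j]))
        ranges[rxn_id] = (min(vmin, vmax), max(vmin, vmax))
    return FvaResult(ranges=ranges, objective_fraction=objective_fraction)


def find_blocked_reactions(model: MetabolicModel, tol: float = DEFAULT_TOL) -> Set[str]:
    """Reactions that cannot carry flux beyond ``tol`` under any steady state.

    Uses objective fraction 0 so "blocked" means infeasible under *any*
    objective, not just along optimal growth.
    """

    result = fva(model, objective_fraction=0.0)
    return {
        rxn_id
        for rxn_id, (vmin, vmax) in result.ranges.items()
        if abs(vmin) <= tol and abs(vmax) <= tol
    }


# ---------------------------------------------------------------------------
# dead-end removal
# ---------------------------------------------------------------------------

def _producers_consumers(model: MetabolicModel):
    """Per metabolite: reactions that can produce / consume it, given bounds."""

    producers: Dict[str, Set[str]] = {m.id: set() for m in model.metabolites}
    consumers: Dict[str, Set[str]] = {m.id: set() for m in model.metabolites}
    for rxn in model.reactions:
        for met_id, coef in rxn.stoichiometry.items():
            if coef > 0:
                if rxn.upper_bound > 0:
                    producers[met_id].add(rxn.id)
                if rxn.lower_bound < 0:
                    consumers[met_id].add(rxn.id)
            elif coef < 0:
                if rxn.upper_bound > 0:
                    consumers[met_id].add(rxn.id)
                if rxn.lower_bound < 0:
                    producers[met_id].add(rxn.id)
    return producers, consumers


def remove_dead_ends(model: MetabolicModel) -> Tuple[MetabolicModel, List[dict]]:
    """Iteratively drop dead-end metabolites and their incident reactions.

    A dead-end metabolite can only be produced or only consumed (directionality
    from bounds; exchange reactions count as both source and sink for their
    metabolite). Removal repeats to fixpoint, which is scan-order independent.
    The objective reaction is never removed; if removal would require it, a
    RuntimeError is raised.
    """

    current = model.copy()
    log: List[dict] = []
    while True:
        producers, consumers = _producers_consumers(current)
        dead: List[str] = [
            m.id
            for m in current.metabolites
            if not producers[m.id] or not consumers[m.id]
        ]
        if not dead:
            break
        doomed: Set[str] = set()
        for met_id in dead:
            incident = {
                r.id for r in current.reactions if met_id in r.stoichiometry
            }
            if current.objective_reaction in incident:
                raise RuntimeError(
                    f"dead-end metabolite {met_id} would remove the objective "
                    f"reaction {current.objective_reaction}"
                )
            doomed |= incident
            log.append({"metabolite": met_id, "removed_reactions": sorted(incident)})
        keep = [r.id for r in current.reactions if r.id not in doomed]
        current = current.subset(keep)
    return current, log


# ---------------------------------------------------------------------------
# leak test
# ---------------------------------------------------------------------------

def leak_test(model: MetabolicModel, tol: float = DEFAULT_TOL) -> List[str]:
    """Metabolites producible from nothing with every exchange closed.

    All exchange bounds are set to [0, 0]; for each metabolite a temporary
    drain is maximized. A mass-balanced network reports an empty list; any
    leak points at a stoichiometric imbalance.
    """

    S, lb, ub = _matrices(model)
    for j, rxn in enumerate(model.reactions):
        if rxn.is_exchange:
            lb[j] = ub[j] = 0.0
    n = len(model.reactions)
    leaking: List[str] = []
    for i, met in enumerate(model.metabolites):
        drain = np.zeros((S.shape[0], 1))
        drain[i, 0] = -1.0
        S_ext = np.hstack([S, drain])
        lb_ext = np.append(lb, 0.0)
        ub_ext = np.append(ub, 1000.0)
        c = np.zeros(n + 1)
        c[n] = -1.0  # maximize drain
        try:
            v = _solve_lp(c, S_ext, lb_ext, ub_ext)
        except InfeasibleModelError:
            continue
        if v[n] > tol:
            leaking.append(met.id)
    return leaking


# ---------------------------------------------------------------------------
# MoMA
# ---------------------------------------------------------------------------

def moma(
    model_perturbed: MetabolicModel,
    v_wt: FluxDistribution,
    variant: str = "quadratic",
    tol: float = DEFAULT_TOL,
) -> FluxDistribution:
    """Minimize the distance to the wild-type flux vector under the perturbed
    constraints; reactions absent from ``v_wt`` are referenced at 0.

    ``variant="quadratic"`` minimizes the squared Euclidean distance (a QP);
    ``variant="linear"`` minimizes the L1 distance via nonnegative
    forward/reverse deviation splitting (an LP).
    """

    S, lb, ub = _matrices(model_perturbed)
    n = len(model_perturbed.reactions)
    w = np.array([v_wt.get(r.id, 0.0) for r in model_perturbed.reactions])

    if variant == "quadratic":
        v = _moma_qp(S, lb, ub, w)
    elif variant == "linear":
        v = _moma_lp(S, lb, ub, w)
    else:
        raise ValueError(f"unknown MoMA variant {variant!r}")

    obj = model_perturbed.objective_reaction
    fluxes = {r.id: float(x) for r, x in zip(model_perturbed.reactions, v)}
    return FluxDistribution(fluxes=fluxes, objective_value=fluxes.get(obj, 0.0))


def _moma_qp(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, w: np.ndarray) -> np.ndarray:
    import osqp
    from scipy import sparse

    n = len(w)
    P = sparse.csc_matrix(2.0 * sparse.eye(n))
    q = -2.0 * w
    A = sparse.vstack([sparse.csc_matrix(S), sparse.eye(n)], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    prob = osqp.OSQP()
    prob.setup(P, q, A, l, u, verbose=False, eps_abs=1e-10, eps_rel=1e-10,
               max_iter=200000, polishing=True)
    res = prob.solve()
    if "solved" not in res.info.status:
        raise InfeasibleModelError("MoMA quadratic program failed", res.info.status)
    # clip tiny constraint violations back into bounds
    return np.clip(res.x, lb, ub)


def _moma_lp(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, w: np.ndarray) -> np.ndarray:
    # variables: [v, d+, d-] with v - w = d+ - d-, d± >= 0; minimize sum d+ + d-
    n = len(w)
    S_ext = np.hstack([S, np.zeros((S.shape[0], 2 * n))])
    dev = np.hstack([np.eye(n), -np.eye(n), np.eye(n)])  # v - d+ + d- = w
    A_eq = np.vstack([S_ext, dev])
    b_eq = np.concatenate([np.zeros(S.shape[0]), w])
    c = np.concatenate([np.zeros(n), np.ones(2 * n)])
    bounds = list(zip(lb, ub)) + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise InfeasibleModelError("MoMA linear program failed", res.message.strip())
    return res.x[:n]


# ---------------------------------------------------------------------------
# metabolic tasks
# ---------------------------------------------------------------------------

def check_metabolic_task(
    model: MetabolicModel, task: MetabolicTask, tol: float = DEFAULT_TOL
) -> bool:
    """True iff every task output is producible from the task inputs alone.

    All exchanges are closed, temporary supplies are opened for the inputs at
    their stated maximum rates, and a temporary sink is added per output; the
    task passes iff each output sink can carry flux above ``tol``.
    """

    for met_id in list(task.inputs) + list(task.outputs):
        if not model.has_metabolite(met_id):
            raise KeyError(f"task {task.id}: unknown metabolite {met_id!r}")
    S, lb, ub = _matrices(model)
    for j, rxn in enumerate(model.reactions):
        if rxn.is_exchange:
            lb[j] = ub[j] = 0.0
    n = len(model.reactions)
    met_index = model._met_index
    cols = []
    col_lb, col_ub = [], []
    for met_id, rate in task.inputs.items():
        col = np.zeros(S.shape[0])
        col[met_index[met_id]] = 1.0  # supply
        cols.append(col)
        col_lb.append(0.0)
        col_ub.append(float(rate))
    sink_pos = {}
    for k, met_id in enumerate(sorted(task.outputs)):
        col = np.zeros(S.shape[0])
        col[met_index[met_id]] = -1.0  # sink
        sink_pos[met_id] = n + len(task.inputs) + k
        cols.append(col)
        col_lb.append(0.0)
        col_ub.append(1000.0)
    S_ext = np.hstack([S] + [c[:, None] for c in cols]) if cols else S
    lb_ext = np.concatenate([lb, col_lb])
    ub_ext = np.concatenate([ub, col_ub])
    for met_id in sorted(task.outputs):
        c = np.zeros(S_ext.shape[1])
        c[sink_pos[met_id]] = -1.0
        try:
            v = _solve_lp(c, S_ext, lb_ext, ub_ext)
        except InfeasibleModelError:
            return False
        if v[sink_pos[met_id]] <= tol:
            return False
    return True


def load_tasks(path) -> List[MetabolicTask]:
    """Read a task catalogue TSV: task_id, inputs (met:rate;...), outputs, expected."""

    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    tasks = []
    for _, row in df.iterrows():
        inputs: Dict[str, float] = {}
        if row["inputs"]:
            for item in row["inputs"].split(";"):
                met, rate = item.split(":")
                inputs[met.strip()] = float(rate)
        outputs = {s.strip() for s in row["outputs"].split(";") if s.strip()}
        tasks.append(
            MetabolicTask(
                id=row["task_id"],
                inputs=inputs,
                outputs=outputs,
                expected=row.get("expected", "pass") or "pass",
            )
        )
    return tasks
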