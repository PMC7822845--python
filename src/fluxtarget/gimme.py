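"""Context-specific model extraction with GIMME, plus model hygiene.

GIMME (Gene Inactivity Moderated by Metabolism and Expression) keeps every
reaction supported by the activity calls and finds the minimal use of
unsupported ("inactive") reactions that still lets the model reach a stated
fraction of its optimal objective. Inactive reactions that carry flux in the
minimizing solution are retained — they are required for essential metabolic
function even without expression evidence. The extracted model is then
cleaned of dead-end metabolites and blocked reactions.

Under binary activity calls the classic GIMME penalty ``threshold −
expression`` collapses to a flat penalty on inactive-reaction flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .network import MediaSpec, MetabolicModel, apply_media
from .omics import ActivityCalls
from .solvers import (
    DEFAULT_TOL,
    InfeasibleModelError,
    MetabolicTask,
    check_metabolic_task,
    fba,
    find_blocked_reactions,
    leak_test,
    remove_dead_ends,
)

__all__ = [
    "GimmeConfig",
    "ModelBuildError",
    "reaction_activity_from_calls",
    "gimme_extract",
    "build_cell_model",
]

ACTIVE = "active"
INACTIVE = "inactive"
NO_GENE = "no_gene"


class ModelBuildError(RuntimeError):
    """Context-specific extraction could not produce a consistent model."""


@dataclass
class GimmeConfig:
    """Extraction parameters.

    biomass_fraction
        Required fraction of the template's optimal objective, in (0, 1].
    inactive_penalty
        Cost per unit of absolute flux through an expression-inactive
        reaction.
    """

    biomass_fraction: float = 0.9
    inactive_penalty: float = 1.0
    tolerance: float = DEFAULT_TOL

    def __post_init__(self) -> None:
        if not 0 < self.biomass_fraction <= 1:
            raise ValueError("biomass_fraction must be in (0, 1]")
        if self.inactive_penalty <= 0:
            raise ValueError("inactive_penalty must be positive")


def reaction_activity_from_calls(
    model: MetabolicModel, calls: ActivityCalls
) -> Dict[str, str]:
    """Label each reaction active / inactive / no_gene from gene activity.

    A reaction is active iff its GPR evaluates true over the active gene set,
    so one expressed isozyme keeps the reaction (and its complete GPR) alive.
    Gene-independent reactions (empty GPR) are labelled ``no_gene``.
    """

    active_genes = calls.active_genes
    labels: Dict[str, str] = {}
    for rxn in model.reactions:
        if rxn.gpr.is_empty:
            labels[rxn.id] = NO_GENE
        elif rxn.gpr.evaluate(active_genes):
            labels[rxn.id] = ACTIVE
        else:
            labels[rxn.id] = INACTIVE
    return labels


def _gimme_lp(
    model: MetabolicModel,
    inactive: List[str],
    fraction: float,
    penalty: float,
) -> Dict[str, float]:
    """Minimize penalty * sum(|v_r|) over inactive reactions subject to
    steady state, bounds, and objective >= fraction * optimum.

    Reversible fluxes are split into nonnegative forward/reverse parts to
    keep the program linear.
    """

    opt = fba(model).objective_value
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    # v = p - m with p, m >= 0
    S_split = np.hstack([S, -S])
    bounds = [(0.0, max(u, 0.0)) for u in ub] + [(0.0, max(-l, 0.0)) for l in lb]
    c = np.zeros(2 * n)
    inactive_set = set(inactive)
    for j, rxn in enumerate(model.reactions):
        if rxn.id in inactive_set:
            c[j] = penalty
            c[n + j] = penalty
    obj = np.zeros(2 * n)
    j_obj = model._rxn_index[model.objective_reaction]
    obj[j_obj] = 1.0
    obj[n + j_obj] = -1.0
    # also enforce original lower bounds where positive / upper where negative
    A_ub_rows = [-obj]
    b_ub = [-fraction * opt]
    for j in range(n):
        if lb[j] > 0:  # forced forward flux
            row = np.zeros(2 * n)
            row[j], row[n + j] = -1.0, 1.0
            A_ub_rows.append(row)
            b_ub.append(-lb[j])
        if ub[j] < 0:  # forced reverse flux
            row = np.zeros(2 * n)
            row[j], row[n + j] = 1.0, -1.0
            A_ub_rows.append(row)
            b_ub.append(ub[j])
    res = linprog(
        c,
        A_eq=S_split,
        b_eq=np.zeros(S.shape[0]),
        A_ub=np.vstack(A_ub_rows),
        b_ub=np.array(b_ub),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise ModelBuildError(
            f"GIMME program infeasible on {model.id}: {res.message.strip()}"
        )
    v = res.x[:n] - res.x[n:]
    return {r.id: float(x) for r, x in zip(model.reactions, v)}


def gimme_extract(
    template: MetabolicModel,
    activity: Dict[str, str],
    config: Optional[GimmeConfig] = None,
) -> MetabolicModel:
    """Extract the context-specific submodel.

    Keeps all active and gene-independent reactions plus any inactive
    reaction that carries flux in the penalty-minimizing solution, then
    removes dead ends and blocked reactions. The output is guaranteed to
    reach ``biomass_fraction`` of the template optimum.
    """

    config = config or GimmeConfig()
    try:
        template_opt = fba(template).objective_value
    except InfeasibleModelError as exc:
        raise ModelBuildError(f"template {template.id} is infeasible: {exc}") from exc

    inactive = [r for r, label in activity.items() if label == INACTIVE]
    solution = _gimme_lp(
        template, inactive, config.biomass_fraction, config.inactive_penalty
    )
    keep = [
        rxn.id
        for rxn in template.reactions
        if activity.get(rxn.id, NO_GENE) != INACTIVE
        or abs(solution[rxn.id]) > config.tolerance
    ]
    sub = template.subset(keep, id=f"{template.id}_context")
    sub, _ = remove_dead_ends(sub)
    blocked = find_blocked_reactions(sub, tol=config.tolerance)
    if blocked:
        sub = sub.subset([r for r in sub.reaction_ids if r not in blocked])

    out_opt = fba(sub).objective_value
    if out_opt < config.biomass_fraction * template_opt - 1e-6:
        raise ModelBuildError(
            f"extracted model reaches {out_opt:.6g} < required "
            f"{config.biomass_fraction * template_opt:.6g}"
        )
    return sub


def build_cell_model(
    template: MetabolicModel,
    calls: ActivityCalls,
    media: MediaSpec,
    tasks: Optional[List[MetabolicTask]] = None,
    config: Optional[GimmeConfig] = None,
) -> Tuple[MetabolicModel, dict]:
    """Full build pipeline: media -> GIMME -> hygiene -> leak test -> tasks.

    Returns the model plus a build report with counts, the reaction-activity
    breakdown, the leak list and per-task outcomes. A failing expected-pass
    task is flagged in the report but does not abort the build.
    """

    config = config or GimmeConfig()
    constrained = apply_media(template, media)
    activity = reaction_activity_from_calls(constrained, calls)
    model = gimme_extract(constrained, activity, config)
    leaks = leak_test(model, tol=config.tolerance)

    task_results = []
    n_failed_expected = 0
    for task in tasks or []:
        try:
            passed = check_metabolic_task(model, task, tol=config.tolerance)
            outcome = "pass" if passed else "fail"
        except KeyError:
            # task metabolites pruned from this context: cannot run
            outcome = "not_applicable"
            passed = None
        if task.expected == "pass" and outcome == "fail":
            n_failed_expected += 1
        task_results.append(
            {"task_id": task.id, "outcome": outcome, "expected": task.expected}
        )

    removed = sorted(set(template.reaction_ids) - set(model.reaction_ids))
    report = {
        "template_id": template.id,
        "model_id": model.id,
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "n_genes": len(model.genes),
        "n_removed_reactions": len(removed),
        "removed_reactions": removed,
        "activity_counts": {
            label: sum(1 for v in activity.values() if v == label)
            for label in (ACTIVE, INACTIVE, NO_GENE)
        },
        "leaks": leaks,
        "task_results": task_results,
        "n_tasks_failed_expected_pass": n_failed_expected,
        "biomass_fraction": config.biomass_fraction,
    }
    return model, report
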