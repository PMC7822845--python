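"""Qualitative model validation: nutrient sweeps, conditional nutrient
dependency, forced-flux responses, and literature-behavior suites.

These procedures mirror how context-specific metabolic models are sanity
checked against physiology: growth should collapse when an essential
nutrient is removed, forcing pyruvate dehydrogenase flux should divert
pyruvate away from lactate secretion, and glutamine should matter only when
glucose is scarce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import MetabolicModel
from .perturbation import DEFAULT_REL_TOL, disabled_reactions_for_gene
from .solvers import DEFAULT_TOL, InfeasibleModelError, fba

__all__ = [
    "SweepResult",
    "BehaviorSpec",
    "nutrient_sweep",
    "conditional_dependency",
    "forced_flux_response",
    "run_behavior_suite",
    "load_behavior_specs",
]


def _growth(model: MetabolicModel) -> Tuple[float, bool]:
    """FBA growth, with infeasible models recorded as zero growth."""

    try:
        return fba(model).objective_value, True
    except InfeasibleModelError:
        return 0.0, False


@dataclass
class SweepResult:
    """Growth response to a varied uptake rate.

    At each grid point the uptake bound is perturbed over a small local
    window of ``window_n`` equally spaced values and the mean/sd of the FBA
    growth over the window is reported.
    """

    exchange_id: str
    grid: np.ndarray
    mean_growth: np.ndarray
    sd_growth: np.ndarray
    infeasible_points: List[float] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "uptake": self.grid,
                "mean_growth": self.mean_growth,
                "sd_growth": self.sd_growth,
            }
        )


def nutrient_sweep(
    model: MetabolicModel,
    exchange_id: str,
    grid: Sequence[float],
    window_n: int = 5,
    window_step: float = 0.1,
) -> SweepResult:
    """Vary one nutrient's maximum uptake and record growth mean/sd.

    The window spans ``window_n`` uptake values centered on each grid point,
    spaced ``window_step`` apart (e.g. 3.0 -> {3.2, 3.1, 3.0, 2.9, 2.8});
    with ``window_n=1`` the sweep is pointwise FBA. Negative window values
    are clamped to zero uptake.
    """

    grid = np.asarray(sorted(grid), dtype=float)
    if not model.has_reaction(exchange_id):
        raise KeyError(f"exchange {exchange_id!r} not in model")
    means, sds = [], []
    infeasible = []
    half = (window_n - 1) / 2.0
    offsets = (np.arange(window_n) - half) * window_step
    for point in grid:
        growths = []
        for uptake in point + offsets:
            uptake = max(uptake, 0.0)
            work = model.copy()
            work.reaction(exchange_id).lower_bound = -uptake
            g, feasible = _growth(work)
            if not feasible:
                infeasible.append(float(point))
            growths.append(g)
        means.append(float(np.mean(growths)))
        sds.append(float(np.std(growths)))
    return SweepResult(
        exchange_id=exchange_id,
        grid=grid,
        mean_growth=np.array(means),
        sd_growth=np.array(sds),
        infeasible_points=infeasible,
    )


def conditional_dependency(
    model: MetabolicModel,
    exchange_a: str,
    exchange_b: str,
    grid_a: Sequence[float],
    grid_b: Sequence[float],
    rel_tol: float = DEFAULT_REL_TOL,
) -> Tuple[pd.DataFrame, dict]:
    """Full-factorial growth surface over two nutrient uptake grids.

    The summary reports, per level of nutrient A, whether varying nutrient B
    changes growth (beyond ``rel_tol`` relative spread), and whether that
    dependence is *conditional* — present only below some A availability
    threshold (e.g. glutamine mattering only under glucose limitation).
    """

    for ex in (exchange_a, exchange_b):
        if not model.has_reaction(ex):
            raise KeyError(f"exchange {ex!r} not in model")
    rows = []
    for a in sorted(grid_a):
        for b in sorted(grid_b):
            work = model.copy()
            work.reaction(exchange_a).lower_bound = -float(a)
            work.reaction(exchange_b).lower_bound = -float(b)
            g, _ = _growth(work)
            rows.append((float(a), float(b), g))
    surface = pd.DataFrame(rows, columns=["uptake_a", "uptake_b", "growth"])
    affected_levels = []
    for a, chunk in surface.groupby("uptake_a"):
        gmax, gmin = chunk["growth"].max(), chunk["growth"].min()
        spread = (gmax - gmin) / gmax if gmax > DEFAULT_TOL else (
            1.0 if gmax - gmin > DEFAULT_TOL else 0.0
        )
        if spread > rel_tol:
            affected_levels.append(float(a))
    unaffected = sorted(set(surface["uptake_a"]) - set(affected_levels))
    conditional = bool(affected_levels) and bool(unaffected) and (
        max(affected_levels) < min(unaffected)
    )
    summary = {
        "b_affects_growth_at_a": sorted(affected_levels),
        "b_no_effect_at_a": unaffected,
        "conditional_on_low_a": conditional,
        "a_threshold": max(affected_levels) if affected_levels else None,
    }
    return surface, summary


def forced_flux_response(
    model: MetabolicModel,
    forced_reaction: str,
    levels: Sequence[float],
    observed_reaction: str,
) -> pd.DataFrame:
    """Force increasing flux through one reaction and watch another.

    The forced reaction's lower bound is set to each level; the observed
    reaction's FBA flux is recorded. Infeasible levels are flagged. A
    ``trend`` attribute on the frame summarizes the response direction.
    """

    for rxn_id in (forced_reaction, observed_reaction):
        if not model.has_reaction(rxn_id):
            raise KeyError(f"reaction {rxn_id!r} not in model")
    rows = []
    for level in sorted(levels):
        work = model.copy()
        rxn = work.reaction(forced_reaction)
        rxn.lower_bound = float(level)
        if rxn.upper_bound < level:
            rxn.upper_bound = float(level)
        try:
            sol = fba(work)
            rows.append((float(level), sol[observed_reaction], True))
        except InfeasibleModelError:
            rows.append((float(level), np.nan, False))
    out = pd.DataFrame(rows, columns=["forced_level", "observed_flux", "feasible"])
    ok = out[out["feasible"]]
    if len(ok) >= 2:
        first, last = ok["observed_flux"].iloc[0], ok["observed_flux"].iloc[-1]
        if last < first - DEFAULT_TOL:
            out.attrs["trend"] = "decreasing"
        elif last > first + DEFAULT_TOL:
            out.attrs["trend"] = "increasing"
        else:
            out.attrs["trend"] = "flat"
    else:
        out.attrs["trend"] = "undetermined"
    return out


@dataclass
class BehaviorSpec:
    """One literature-derived qualitative expectation.

    perturbation_type: ``remove_nutrient`` (close an exchange's uptake),
    ``knockout_gene`` (disable reactions via GPR), or ``force_flux``
    (``reaction:level`` lower-bound forcing). The observable is ``growth`` or
    a reaction id; the expectation is one of zero / decreased / increased /
    unchanged / nonzero relative to the unperturbed model.
    """

    description: str
    perturbation_type: str
    perturbation_arg: str
    observable: str
    expected: str


def load_behavior_specs(path) -> List[BehaviorSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        BehaviorSpec(
            description=row["description"],
            perturbation_type=row["perturbation_type"],
            perturbation_arg=row["perturbation_arg"],
            observable=row["observable"],
            expected=row["expected"],
        )
        for _, row in df.iterrows()
    ]


def _qualitative(observed: float, baseline: float, rel_tol: float,
                 abs_tol: float) -> str:
    if abs(observed) <= abs_tol:
        return "zero"
    if abs(baseline) <= abs_tol:
        return "increased"
    ratio = observed / baseline
    if ratio < 1 - rel_tol:
        return "decreased"
    if ratio > 1 + rel_tol:
        return "increased"
    return "unchanged"


#: expected -> observed -> verdict; "partial" covers adjacent outcomes
_VERDICT = {
    ("zero", "zero"): "agree",
    ("zero", "decreased"): "partial",
    ("decreased", "decreased"): "agree",
    ("decreased", "zero"): "agree",  # zero is the strongest decrease
    ("decreased", "unchanged"): "partial",
    ("increased", "increased"): "agree",
    ("increased", "unchanged"): "partial",
    ("unchanged", "unchanged"): "agree",
    ("unchanged", "decreased"): "partial",
    ("unchanged", "increased"): "partial",
}


def run_behavior_suite(
    model: MetabolicModel,
    specs: Sequence[BehaviorSpec],
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_TOL,
) -> List[dict]:
    """Execute every behavior spec; unresolvable specs are reported as errors
    and the suite continues."""

    baseline = fba(model)
    results = []
    for spec in specs:
        try:
            work = model.copy()
            if spec.perturbation_type == "remove_nutrient":
                work.reaction(spec.perturbation_arg).lower_bound = 0.0
            elif spec.perturbation_type == "knockout_gene":
                for rxn_id in disabled_reactions_for_gene(work, spec.perturbation_arg):
                    rxn = work.reaction(rxn_id)
                    rxn.lower_bound = rxn.upper_bound = 0.0
            elif spec.perturbation_type == "force_flux":
                rxn_id, level = spec.perturbation_arg.split(":")
                rxn = work.reaction(rxn_id)
                rxn.lower_bound = float(level)
                rxn.upper_bound = max(rxn.upper_bound, float(level))
            else:
                raise ValueError(
                    f"unknown perturbation type {spec.perturbation_type!r}"
                )
            obs_id = (model.objective_reaction if spec.observable == "growth"
                      else spec.observable)
            base_value = baseline[obs_id]
            try:
                observed_value = fba(work)[obs_id]
            except InfeasibleModelError:
                observed_value = 0.0
            outcome = _qualitative(observed_value, base_value, rel_tol, abs_tol)
            if spec.expected == "nonzero":
                verdict = "agree" if outcome != "zero" else "disagree"
            else:
                verdict = _VERDICT.get((spec.expected, outcome), "disagree")
            results.append(
                {
                    "description": spec.description,
                    "expected": spec.expected,
                    "observed": outcome,
                    "observed_value": observed_value,
                    "baseline_value": base_value,
                    "verdict": verdict,
                }
            )
        except (KeyError, ValueError) as exc:
            results.append(
                {
                    "description": spec.description,
                    "expected": spec.expected,
                    "observed": None,
                    "verdict": "error",
                    "error": str(exc),
                }
            )
    return results
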