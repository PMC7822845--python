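"""Shared fixtures: small hand-built networks with closed-form solutions."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from fluxtarget.gpr import parse_gpr
from fluxtarget.network import MetabolicModel, Metabolite, Reaction
from fluxtarget.synth import make_scenario, make_toy_template


def build_model(model_id, reactions, objective):
    """Assemble a model from (id, stoich, lb, ub, gpr) tuples."""

    met_ids = sorted({m for _, stoich, *_ in reactions for m in stoich})
    mets = [Metabolite(m, compartment=m.rsplit("_", 1)[-1]) for m in met_ids]
    rxns = [
        Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                 gpr=parse_gpr(gpr))
        for rid, stoich, lb, ub, gpr in reactions
    ]
    return MetabolicModel(id=model_id, metabolites=mets, reactions=rxns,
                          objective_reaction=objective)


@pytest.fixture
def chain_model():
    """EX_A (uptake <= 10) -> R1: A->B -> R2: B->biomass; optimum = min capacity."""

    return build_model(
        "chain",
        [
            ("EX_A", {"a_e": -1}, -10.0, 1000.0, ""),
            ("R1", {"a_e": -1, "b_c": 1}, 0.0, 10.0, "g1"),
            ("R2", {"b_c": -1}, 0.0, 10.0, "g2"),
        ],
        "R2",
    )


@pytest.fixture
def bottleneck_model():
    """Chain with R1 capacity 3: the optimum is the bottleneck value."""

    return build_model(
        "bottleneck",
        [
            ("EX_A", {"a_e": -1}, -10.0, 1000.0, ""),
            ("R1", {"a_e": -1, "b_c": 1}, 0.0, 3.0, "g1"),
            ("R2", {"b_c": -1}, 0.0, 10.0, "g2"),
        ],
        "R2",
    )


@pytest.fixture
def two_path_model():
    """Two parallel isozyme-like routes A->B feeding a biomass drain."""

    return build_model(
        "two_path",
        [
            ("EX_A", {"a_e": -1}, -10.0, 1000.0, ""),
            ("R1", {"a_e": -1, "b_c": 1}, 0.0, 10.0, "g1"),
            ("R2", {"a_e": -1, "b_c": 1}, 0.0, 10.0, "g2"),
            ("R3", {"b_c": -1}, 0.0, 20.0, "g3"),
        ],
        "R3",
    )


@pytest.fixture(scope="session")
def template():
    return make_toy_template(seed=0, size="small")


@pytest.fixture(scope="session")
def scenario():
    return make_scenario(seed=7)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def lp_vertices(S, lb, ub, tol=1e-9):
    """Enumerate the vertices of {v: Sv=0, lb<=v<=ub} by fixing variable
    subsets at their bounds and solving the remaining square system."""

    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    d = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, fixed] @ np.array(bounds_choice)
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            if np.max(np.abs(A @ sol - rhs)) > 1e-7:
                continue
            v = np.zeros(n)
            v[list(fixed)] = bounds_choice
            v[free] = sol
            if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7):
                vertices.append(np.clip(v, lb, ub))
    return vertices


def brute_force_fba(model):
    """LP optimum via vertex enumeration (independent of the LP solver)."""

    S = model.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    j = model.reaction_ids.index(model.objective_reaction)
    verts = lp_vertices(S, lb, ub)
    assert verts, "no vertex found"
    return max(v[j] for v in verts)


def gpr_truth_table(text, genes):
    """Brute-force truth table of a parenthesized and/or expression by
    direct python eval over every gene subset."""

    import re

    table = {}
    for assignment in itertools.product([False, True], repeat=len(genes)):
        env = dict(zip(genes, assignment))

        def repl(match):
            tok = match.group(0)
            if tok.lower() in ("and", "or"):
                return tok.lower()
            return str(env[tok])

        table[assignment] = eval(re.sub(r"[^\s()]+", repl, text))
    return table
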