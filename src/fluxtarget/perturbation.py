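"""In silico drug-target perturbation: GPR-driven knockouts, MoMA flux
prediction, flux-change classification and essentiality screening.

Deleting a gene disables exactly those reactions whose GPR becomes false
without it — a reaction backed by an expressed isozyme (OR sibling) survives,
a broken complex (AND member) does not. Post-knockout fluxes come from MoMA
against a cached wild-type FBA solution, and each reaction is classified as
down / up / unchanged from the ratio of perturbed to wild-type flux
magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .network import MetabolicModel
from .solvers import DEFAULT_TOL, FluxDistribution, InfeasibleModelError, fba, moma

__all__ = [
    "DrugAnnotation",
    "KnockoutResult",
    "FluxChangeTable",
    "load_drug_annotations",
    "map_drug_targets",
    "gene_knockout",
    "filter_effective_targets",
    "classify_flux_changes",
    "essentiality_screen",
    "essentiality_pr_curve",
]

CLASS_DOWN = "down"
CLASS_UP = "up"
CLASS_UNCHANGED = "unchanged"

#: Default relative tolerance on flux ratios for calling a change.
DEFAULT_REL_TOL = 0.05

WITHDRAWN = "withdrawn"


@dataclass
class DrugAnnotation:
    """A drug/compound with clinical status and its target gene ids."""

    drug: str
    status: str  # launched | phase | preclinical | withdrawn
    targets: List[str]


def load_drug_annotations(path, drop_withdrawn: bool = True) -> List[DrugAnnotation]:
    """Read drug annotations (TSV: drug, status, targets pipe-separated).

    Withdrawn drugs and their annotations are removed at load.
    """

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        status = row["status"].strip().lower()
        if drop_withdrawn and status == WITHDRAWN:
            continue
        targets = [t.strip() for t in row["targets"].split("|") if t.strip()]
        out.append(DrugAnnotation(drug=row["drug"], status=status, targets=targets))
    return out


def map_drug_targets(
    annotations: Iterable[DrugAnnotation], model: MetabolicModel
) -> Dict[str, List[str]]:
    """Map gene id -> drugs targeting it, restricted to genes in the model."""

    mapping: Dict[str, List[str]] = {}
    for ann in annotations:
        if ann.status == WITHDRAWN:
            continue
        for gene in ann.targets:
            if gene in model.genes:
                mapping.setdefault(gene, []).append(ann.drug)
    return mapping


@dataclass
class KnockoutResult:
    """Outcome of a single-gene deletion."""

    gene: str
    disabled_reactions: Set[str]
    v_ko: FluxDistribution
    growth_ratio: float

    @property
    def silent(self) -> bool:
        """True when no reaction was disabled (isozyme-backed target)."""

        return not self.disabled_reactions


def disabled_reactions_for_gene(model: MetabolicModel, gene: str) -> Set[str]:
    """Reactions whose GPR evaluates false once ``gene`` is removed."""

    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model {model.id}")
    surviving = model.genes - {gene}
    return {
        r.id
        for r in model.reactions
        if gene in r.gpr.genes and not r.gpr.evaluate(surviving)
    }


def gene_knockout(
    model: MetabolicModel,
    gene: str,
    v_wt: Optional[FluxDistribution] = None,
    moma_variant: str = "quadratic",
) -> KnockoutResult:
    """Delete ``gene``, close its disabled reactions and re-solve with MoMA.

    A knockout disabling nothing is returned as-is (silent) with the
    wild-type fluxes — the effective-target filter downstream needs these
    records too.
    """

    if v_wt is None:
        v_wt = fba(model)
    disabled = disabled_reactions_for_gene(model, gene)
    if not disabled:
        return KnockoutResult(
            gene=gene, disabled_reactions=set(), v_ko=v_wt, growth_ratio=1.0
        )
    perturbed = model.copy()
    for rxn_id in disabled:
        rxn = perturbed.reaction(rxn_id)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    v_ko = moma(perturbed, v_wt, variant=moma_variant)
    wt_growth = v_wt.objective_value
    ratio = v_ko.objective_value / wt_growth if abs(wt_growth) > 0 else 0.0
    return KnockoutResult(
        gene=gene,
        disabled_reactions=disabled,
        v_ko=v_ko,
        growth_ratio=max(ratio, 0.0),
    )


def filter_effective_targets(knockouts: Iterable[KnockoutResult]) -> Set[str]:
    """Genes whose deletion blocks at least one associated reaction."""

    return {ko.gene for ko in knockouts if ko.disabled_reactions}


@dataclass
class FluxChangeTable:
    """Per-reaction wild-type vs knockout flux with a down/up/unchanged class.

    ``table`` columns: reaction_id (index), v_wt, v_ko, ratio, class.
    The ratio is perturbed/wild-type on flux magnitudes; it is NaN where the
    wild-type flux is (numerically) zero. ``sign_flips`` lists reactions whose
    flux changed direction, which the magnitude-based classes do not encode.
    """

    table: pd.DataFrame
    sign_flips: List[str] = field(default_factory=list)

    def reactions_in_class(self, cls: str) -> Set[str]:
        return set(self.table.index[self.table["class"] == cls])

    def class_of(self, rxn_id: str) -> str:
        return str(self.table.loc[rxn_id, "class"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "reaction_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FluxChangeTable":
        return cls(table=pd.read_csv(path, sep="\t", index_col="reaction_id"))


def classify_flux_changes(
    v_wt: FluxDistribution,
    v_ko: FluxDistribution,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_TOL,
    signed: bool = False,
) -> FluxChangeTable:
    """Classify every reaction as down / up / unchanged after a knockout.

    Comparison is on flux magnitudes by default: for a reversible reaction,
    sign encodes direction, not activity, so a sign change alone is not an
    activity change (it is reported in ``sign_flips``). With ``signed=True``
    raw signed fluxes are compared instead.
    """

    rows = []
    flips = []
    for rxn_id in v_wt.fluxes:
        wt = v_wt[rxn_id]
        ko = v_ko.get(rxn_id, 0.0)
        if wt * ko < 0 and abs(wt) > abs_tol and abs(ko) > abs_tol:
            flips.append(rxn_id)
        m_wt = wt if signed else abs(wt)
        m_ko = ko if signed else abs(ko)
        if abs(m_wt) <= abs_tol:
            cls = CLASS_UP if abs(m_ko) > abs_tol else CLASS_UNCHANGED
            ratio = np.nan
        else:
            ratio = m_ko / m_wt
            if abs(m_ko - m_wt) <= abs_tol or (1 - rel_tol) <= ratio <= (1 + rel_tol):
                cls = CLASS_UNCHANGED
            elif m_ko < m_wt * (1 - rel_tol):
                cls = CLASS_DOWN
            else:
                cls = CLASS_UP
        rows.append((rxn_id, wt, ko, ratio, cls))
    table = pd.DataFrame(
        rows, columns=["reaction_id", "v_wt", "v_ko", "ratio", "class"]
    ).set_index("reaction_id")
    return FluxChangeTable(table=table, sign_flips=flips)


def essentiality_screen(
    model: MetabolicModel,
    genes: Optional[Iterable[str]] = None,
    v_wt: Optional[FluxDistribution] = None,
    moma_variant: str = "quadratic",
    essential_cutoff: float = 0.01,
    reduced_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Single-gene deletion screen classifying growth impact.

    Returns a frame indexed by gene with ``growth_ratio`` and ``essentiality``
    in {essential, reduced, nonessential}: essential below 1% of wild-type
    growth, reduced below 50%.
    """

    if genes is None:
        genes = sorted(model.genes)
    if v_wt is None:
        v_wt = fba(model)
    rows = []
    for gene in genes:
        ko = gene_knockout(model, gene, v_wt, moma_variant=moma_variant)
        if ko.growth_ratio < essential_cutoff:
            cls = "essential"
        elif ko.growth_ratio < reduced_cutoff:
            cls = "reduced"
        else:
            cls = "nonessential"
        rows.append((gene, ko.growth_ratio, cls))
    return pd.DataFrame(
        rows, columns=["gene", "growth_ratio", "essentiality"]
    ).set_index("gene")


def essentiality_pr_curve(
    growth_ratios: Dict[str, float], reference_positive: Set[str]
) -> Tuple[pd.DataFrame, float]:
    """Precision-recall curve for essentiality prediction.

    Genes are ranked by ascending growth ratio (most growth-impairing first);
    precision and recall are evaluated at every prefix of the ranking and the
    area is the trapezoid over (recall, precision), anchored at recall 0 with
    the first prefix's precision.
    """

    if not reference_positive:
        raise ValueError("reference essential-gene set is empty")
    ordered = sorted(growth_ratios, key=lambda g: (growth_ratios[g], g))
    tp = 0
    rows = []
    n_ref = len(reference_positive)
    for k, gene in enumerate(ordered, start=1):
        if gene in reference_positive:
            tp += 1
        rows.append((gene, growth_ratios[gene], tp / k, tp / n_ref))
    curve = pd.DataFrame(
        rows, columns=["gene", "growth_ratio", "precision", "recall"]
    )
    recalls = np.concatenate([[0.0], curve["recall"].to_numpy()])
    precisions = np.concatenate(
        [[curve["precision"].iloc[0]], curve["precision"].to_numpy()]
    )
    auc = float(np.trapezoid(precisions, recalls))
    return curve, auc
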