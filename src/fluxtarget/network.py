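"""Data model for genome-scale constraint-based metabolic models.

Conventions
-----------
* Exchange reactions are written ``met_e <=> (nothing)``: negative flux is
  uptake, positive flux is secretion.
* Reversibility is encoded purely by bounds (``lower_bound < 0``), never by a
  separate flag.
* Gene identifiers are opaque strings assumed already harmonized across data
  sources.

The JSON dialect follows the community constraint-based model exchange format
(top-level ``id``/``metabolites``/``reactions``/``genes``; reactions carry
``gene_reaction_rule`` text), so files written here load in cobrapy and vice
versa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Set

import numpy as np

from .gpr import GPRRule, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediaSpec",
    "ModelFormatError",
    "MediaError",
    "read_model",
    "write_model",
    "apply_media",
    "reactions_of_gene",
]

#: Sentinel "unbounded" flux magnitude (mmol/gDW/hr), matching community models.
DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """Model file violates the expected schema."""


class MediaError(ValueError):
    """Media specification refers to something that is not an open exchange."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    annotation: dict = field(default_factory=dict)


@dataclass
class Reaction:
    """A (possibly reversible) biochemical reaction.

    ``stoichiometry`` maps metabolite id to its signed coefficient (negative =
    consumed at positive flux). Bounds are in mmol/gDW/hr.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRRule = field(default_factory=GPRRule)
    name: str = ""
    subsystem: str = ""
    annotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} exceeds "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions touch exactly one metabolite."""

        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry),
                       annotation=dict(self.annotation))


@dataclass
class MediaSpec:
    """Environmental nutrient availability.

    ``uptake_bounds`` maps exchange-reaction id to the maximum uptake rate
    (nonnegative; applied as a negative lower bound). ``free_metabolites``
    lists basal metabolite ids (water, oxygen, protons, ...) whose exchanges
    stay unconstrained for uptake.
    """

    uptake_bounds: Dict[str, float] = field(default_factory=dict)
    free_metabolites: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for rxn_id, rate in self.uptake_bounds.items():
            if rate < 0:
                raise MediaError(f"uptake rate for {rxn_id} must be >= 0, got {rate}")


class MetabolicModel:
    """A stoichiometric model: metabolites x reactions, bounds, GPRs, objective."""

    def __init__(
        self,
        id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        genes: Optional[Set[str]] = None,
        objective_reaction: str = "",
        annotation: Optional[dict] = None,
    ) -> None:
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.annotation = dict(annotation or {})
        gpr_genes: Set[str] = set()
        for rxn in self.reactions:
            gpr_genes |= rxn.gpr.genes
        self.genes: Set[str] = set(genes) if genes is not None else gpr_genes
        missing = gpr_genes - self.genes
        if missing:
            raise ModelFormatError(
                f"GPR genes absent from model gene list: {sorted(missing)}"
            )
        self.objective_reaction = objective_reaction
        self._index()
        if objective_reaction and objective_reaction not in self._rxn_index:
            raise ModelFormatError(
                f"objective reaction {objective_reaction!r} not in model"
            )
        met_ids = {m.id for m in self.metabolites}
        for rxn in self.reactions:
            unknown = set(rxn.stoichiometry) - met_ids
            if unknown:
                raise ModelFormatError(
                    f"reaction {rxn.id} references unknown metabolites {sorted(unknown)}"
                )

    def _index(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelFormatError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelFormatError("duplicate reaction ids")

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (|metabolites| x |reactions|)."""

        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                S[self._met_index[met_id], j] = coef
        return S

    def copy(self, id: Optional[str] = None) -> "MetabolicModel":
        return MetabolicModel(
            id=id or self.id,
            metabolites=[replace(m, annotation=dict(m.annotation))
                         for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=set(self.genes),
            objective_reaction=self.objective_reaction,
            annotation=dict(self.annotation),
        )

    def subset(self, reaction_ids: Iterable[str], id: Optional[str] = None) -> "MetabolicModel":
        """Submodel keeping the given reactions and their metabolites."""

        keep = set(reaction_ids)
        reactions = [r.copy() for r in self.reactions if r.id in keep]
        used_mets = set()
        for rxn in reactions:
            used_mets |= set(rxn.stoichiometry)
        metabolites = [replace(m, annotation=dict(m.annotation))
                       for m in self.metabolites if m.id in used_mets]
        genes = set()
        for rxn in reactions:
            genes |= rxn.gpr.genes
        return MetabolicModel(
            id=id or self.id,
            metabolites=metabolites,
            reactions=reactions,
            genes=genes,
            objective_reaction=self.objective_reaction,
            annotation=dict(self.annotation),
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions, {len(self.genes)} genes>")


def reactions_of_gene(model: MetabolicModel, gene: str) -> Set[str]:
    """Ids of reactions whose GPR mentions ``gene``."""

    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model {model.id}")
    return {r.id for r in model.reactions if gene in r.gpr.genes}


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

def apply_media(model: MetabolicModel, media: MediaSpec) -> MetabolicModel:
    """Constrain exchange uptake bounds to a nutrient environment.

    Listed exchanges get ``lower_bound = -uptake``; exchanges of basal (free)
    metabolites keep unconstrained uptake; every other exchange is closed for
    uptake. Secretion (upper) bounds and all internal reactions are untouched.
    """

    out = model.copy()
    exchange_ids = {r.id for r in out.reactions if r.is_exchange}
    unknown = set(media.uptake_bounds) - exchange_ids
    if unknown:
        raise MediaError(
            f"media references non-exchange or missing reactions: {sorted(unknown)}"
        )
    for rxn in out.reactions:
        if not rxn.is_exchange:
            continue
        met_id = next(iter(rxn.stoichiometry))
        if rxn.id in media.uptake_bounds:
            rxn.lower_bound = -float(media.uptake_bounds[rxn.id])
        elif met_id in media.free_metabolites:
            rxn.lower_bound = -DEFAULT_BOUND
        else:
            rxn.lower_bound = 0.0
        if rxn.lower_bound > rxn.upper_bound:
            rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)
    return out


# ---------------------------------------------------------------------------
# JSON / SBML I/O
# ---------------------------------------------------------------------------

_REQUIRED_TOP = ("id", "metabolites", "reactions")
_REQUIRED_RXN = ("id", "metabolites", "lower_bound", "upper_bound")


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula is not None else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
                **({"annotation": m.annotation} if m.annotation else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": {k: float(v) for k, v in r.stoichiometry.items()},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "gene_reaction_rule": r.gpr.to_string(),
                "subsystem": r.subsystem,
                "objective_coefficient": 1.0 if r.id == model.objective_reaction else 0.0,
                **({"annotation": r.annotation} if r.annotation else {}),
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in sorted(model.genes)],
        "compartments": {
            c: c for c in sorted({m.compartment for m in model.metabolites if m.compartment})
        },
        **({"annotation": model.annotation} if model.annotation else {}),
        "version": "1",
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    missing = [k for k in _REQUIRED_TOP if k not in data]
    if missing:
        raise ModelFormatError(f"model file missing required keys: {missing}")
    metabolites = []
    for entry in data["metabolites"]:
        if "id" not in entry:
            raise ModelFormatError("metabolite entry without id")
        metabolites.append(
            Metabolite(
                id=entry["id"],
                name=entry.get("name", ""),
                compartment=entry.get("compartment", ""),
                formula=entry.get("formula"),
                charge=entry.get("charge"),
                annotation=entry.get("annotation", {}),
            )
        )
    reactions = []
    objective = ""
    for entry in data["reactions"]:
        missing = [k for k in _REQUIRED_RXN if k not in entry]
        if missing:
            raise ModelFormatError(
                f"reaction entry {entry.get('id', '?')!r} missing keys: {missing}"
            )
        reactions.append(
            Reaction(
                id=entry["id"],
                stoichiometry={k: float(v) for k, v in entry["metabolites"].items()},
                lower_bound=float(entry["lower_bound"]),
                upper_bound=float(entry["upper_bound"]),
                gpr=parse_gpr(entry.get("gene_reaction_rule", "")),
                name=entry.get("name", ""),
                subsystem=entry.get("subsystem", ""),
                annotation=entry.get("annotation", {}),
            )
        )
        if entry.get("objective_coefficient", 0.0):
            objective = entry["id"]
    if not objective:
        raise ModelFormatError(
            "model file missing required keys: ['objective_coefficient "
            "(no reaction marked as objective)']"
        )
    genes = {g["id"] for g in data.get("genes", [])} or None
    return MetabolicModel(
        id=data["id"],
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_reaction=objective,
        annotation=data.get("annotation", {}),
    )


def write_model(model: MetabolicModel, path, format: str = "json") -> None:
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_model(path, format: str = "json") -> MetabolicModel:
    if format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelFormatError(f"not valid JSON: {exc}") from exc
        return _model_from_dict(data)
    if format == "sbml":
        import cobra.io

        return from_cobra(cobra.io.read_sbml_model(str(path)))
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# cobrapy interop (SBML backend and cross-checks)
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy Model (used for SBML I/O and cross-validation)."""

    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment or "c",
            formula=m.formula, charge=m.charge,
        )
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        rule = r.gpr.to_string()
        if rule:
            cr.gene_reaction_rule = rule
    if model.objective_reaction:
        cm.objective = model.objective_reaction
    return cm


def from_cobra(cm) -> MetabolicModel:
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "",
                   formula=m.formula, charge=m.charge)
        for m in cm.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gpr=parse_gpr(r.gene_reaction_rule or ""),
            name=r.name or "",
            subsystem=r.subsystem or "",
        )
        for r in cm.reactions
    ]
    objective = ""
    for r in cm.reactions:
        if r.objective_coefficient:
            objective = r.id
    return MetabolicModel(
        id=cm.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes={g.id for g in cm.genes},
        objective_reaction=objective,
    )
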