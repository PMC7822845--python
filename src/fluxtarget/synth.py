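"""Synthetic toy scenarios with known ground truth.

The generators emulate the statistical structure of the real inputs —
binary presence calls per sample, proteomic abundance quartiles, DEG
direction labels, isozyme/complex GPRs — at toy scale, so the full pipeline
(integration, extraction, knockout screening, PES ranking) runs end-to-end
in seconds with a planted, verifiable answer.

The toy template mirrors central carbon metabolism of a proliferating
T cell: a glucose -> glycolysis chain feeding a pyruvate node that branches
to lactate secretion and a TCA-like cycle, a glutamine -> glutamate ->
alpha-ketoglutarate anaplerotic route with a pyruvate-carboxylase bypass, a
fatty-acid uptake/oxidation branch (used by the naive profile) versus de
novo lipogenesis (effector profile), and a biomass reaction drawing five
precursors. All generators are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .gpr import parse_gpr
from .network import MediaSpec, MetabolicModel, Metabolite, Reaction
from .omics import AbundanceTable, PresenceMatrix
from .perturbation import (
    DrugAnnotation,
    classify_flux_changes,
    disabled_reactions_for_gene,
    gene_knockout,
)
from .scoring import DEGTable
from .solvers import fba

__all__ = [
    "SyntheticScenario",
    "make_toy_template",
    "make_pyruvate_branch",
    "default_media",
    "default_profiles",
    "simulate_omics",
    "simulate_disease",
    "simulate_annotations",
    "make_scenario",
    "write_scenario",
]

#: Default planted drug target: a pyruvate-carrier complex member whose
#: knockout reroutes pyruvate away from the TCA cycle toward lactate and
#: forces glutamine-dependent anaplerosis — both down- and up-reactions.
PLANTED_TARGET = "g_MPC1"

CELL_TYPES = ("naive", "effector")


def _rxn(rid, stoich, gpr="", lb=0.0, ub=1000.0, subsystem="", name=""):
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr=parse_gpr(gpr),
        subsystem=subsystem,
        name=name or rid,
    )


def make_toy_template(seed: int = 0, size: str = "small") -> MetabolicModel:
    """Deterministic toy template model (seed kept for interface symmetry).

    The ``small`` class has ~27 reactions / ~22 metabolites / ~28 genes;
    ``medium`` appends extra decoy pathways with their own genes. Growth is
    positive under the default open bounds and the network passes the leak
    test (no stoichiometric mass creation).
    """

    if size not in ("small", "medium"):
        raise ValueError("size must be 'small' or 'medium'")
    mets = [
        Metabolite("glc_e", "glucose", "e"),
        Metabolite("glc_c", "glucose", "c"),
        Metabolite("g6p_c", "glucose-6-phosphate", "c"),
        Metabolite("f6p_c", "fructose-6-phosphate", "c"),
        Metabolite("pyr_c", "pyruvate", "c"),
        Metabolite("pyr_m", "pyruvate", "m"),
        Metabolite("lac_c", "lactate", "c"),
        Metabolite("lac_e", "lactate", "e"),
        Metabolite("accoa_m", "acetyl-CoA", "m"),
        Metabolite("cit_m", "citrate", "m"),
        Metabolite("akg_m", "alpha-ketoglutarate", "m"),
        Metabolite("oaa_m", "oxaloacetate", "m"),
        Metabolite("nrg_c", "energy equivalent", "c"),
        Metabolite("gln_e", "glutamine", "e"),
        Metabolite("gln_c", "glutamine", "c"),
        Metabolite("glu_c", "glutamate", "c"),
        Metabolite("fa_e", "fatty acid", "e"),
        Metabolite("fa_c", "fatty acid", "c"),
        Metabolite("lipid_c", "membrane lipid", "c"),
        Metabolite("leu_e", "leucine", "e"),
        Metabolite("leu_c", "leucine", "c"),
    ]
    rxns = [
        # exchanges (negative flux = uptake); fatty acids closed by default,
        # the naive medium opens them; glutamine tightly constrained so
        # anaplerosis cannot run on glutamine alone
        _rxn("EX_glc_D_e", {"glc_e": -1}, lb=-10.0, subsystem="Exchange"),
        _rxn("EX_gln_L_e", {"gln_e": -1}, lb=-1.0, subsystem="Exchange"),
        _rxn("EX_fa_e", {"fa_e": -1}, lb=0.0, subsystem="Exchange"),
        _rxn("EX_leu_L_e", {"leu_e": -1}, lb=-2.0, subsystem="Exchange"),
        _rxn("EX_lac_L_e", {"lac_e": -1}, lb=0.0, subsystem="Exchange"),
        # glycolysis
        _rxn("GLCt", {"glc_e": -1, "glc_c": 1}, gpr="g_GLUT1 or g_GLUT3",
             subsystem="Transport"),
        _rxn("HEX1", {"glc_c": -1, "g6p_c": 1}, gpr="g_HK1",
             subsystem="Glycolysis"),
        _rxn("PGI", {"g6p_c": -1, "f6p_c": 1}, gpr="g_GPI", lb=-1000.0,
             subsystem="Glycolysis"),
        _rxn("PYK", {"f6p_c": -1, "pyr_c": 2, "nrg_c": 1},
             gpr="g_PFKM and g_PKM", subsystem="Glycolysis"),
        # pyruvate node
        _rxn("LDH_L", {"pyr_c": -1, "lac_c": 1}, gpr="g_LDHA or g_LDHB",
             lb=-1000.0, subsystem="Fermentation"),
        _rxn("LACt", {"lac_c": -1, "lac_e": 1}, subsystem="Transport"),
        _rxn("PYRtm", {"pyr_c": -1, "pyr_m": 1}, gpr="g_MPC1",
             subsystem="Transport"),
        _rxn("PDHm", {"pyr_m": -1, "accoa_m": 1}, gpr="g_PDHA1 and g_PDHB",
             ub=5.0, subsystem="TCA cycle"),
        _rxn("PCm", {"pyr_m": -1, "oaa_m": 1}, gpr="g_PC",
             subsystem="Anaplerosis"),
        # TCA-like cycle with energy yield
        _rxn("CSm", {"accoa_m": -1, "oaa_m": -1, "cit_m": 1}, gpr="g_CS",
             subsystem="TCA cycle"),
        _rxn("ICDHym", {"cit_m": -1, "akg_m": 1}, gpr="g_IDH2",
             subsystem="TCA cycle"),
        _rxn("AKGDm", {"akg_m": -1, "oaa_m": 1, "nrg_c": 2}, gpr="g_OGDH",
             subsystem="TCA cycle"),
        # glutaminolysis
        _rxn("GLNt", {"gln_e": -1, "gln_c": 1}, gpr="g_SLC1A5",
             subsystem="Transport"),
        _rxn("GLSc", {"gln_c": -1, "glu_c": 1}, gpr="g_GLS",
             subsystem="Glutaminolysis"),
        _rxn("GLUDm", {"glu_c": -1, "akg_m": 0.8}, gpr="g_GLUD1",
             subsystem="Glutaminolysis"),
        # fatty acid branch (naive) vs de novo lipogenesis (effector)
        _rxn("FAt", {"fa_e": -1, "fa_c": 1}, gpr="g_CD36",
             subsystem="Transport"),
        _rxn("FAOm", {"fa_c": -1, "accoa_m": 2, "nrg_c": 1}, gpr="g_CPT1A",
             subsystem="Fatty acid oxidation"),
        _rxn("LIPS", {"fa_c": -1, "lipid_c": 1}, gpr="g_ACSL3",
             subsystem="Lipid synthesis"),
        _rxn("DNL", {"pyr_c": -1, "nrg_c": -1, "lipid_c": 1},
             gpr="g_ACACA and g_FASN", subsystem="Lipid synthesis"),
        # essential amino acid
        _rxn("LEUt", {"leu_e": -1, "leu_c": 1}, gpr="g_LAT1",
             subsystem="Transport"),
        # energy dissipation (maintenance demand)
        _rxn("NRGD", {"nrg_c": -1}, subsystem="Maintenance"),
        # biomass: five precursors in fixed ratios
        _rxn(
            "BIOMASS",
            {"g6p_c": -0.5, "oaa_m": -0.5, "leu_c": -0.3, "lipid_c": -0.3,
             "nrg_c": -1.0},
            subsystem="Biomass",
        ),
    ]
    if size == "medium":
        rng = np.random.default_rng(seed)
        n_extra = 3
        for i in range(1, n_extra + 1):
            mets += [
                Metabolite(f"dx{i}a_c", f"decoy {i}a", "c"),
                Metabolite(f"dx{i}b_c", f"decoy {i}b", "c"),
            ]
            # gene pairs alternate isozyme/complex structure
            op = "or" if rng.random() < 0.5 else "and"
            rxns += [
                _rxn(f"DEC{i}A", {"g6p_c": -1, f"dx{i}a_c": 1},
                     gpr=f"g_DEC{i}A1 {op} g_DEC{i}A2", subsystem="Decoy"),
                _rxn(f"DEC{i}B", {f"dx{i}a_c": -1, f"dx{i}b_c": 1},
                     gpr=f"g_DEC{i}B", subsystem="Decoy"),
                _rxn(f"DM_dx{i}b_c", {f"dx{i}b_c": -1}, subsystem="Decoy"),
            ]
    else:
        # one small decoy side path so decoy DEGs exist at toy scale
        mets += [Metabolite("dx1a_c", "decoy 1a", "c")]
        rxns += [
            _rxn("DEC1A", {"g6p_c": -1, "dx1a_c": 1}, gpr="g_DEC1A",
                 subsystem="Decoy"),
            _rxn("DM_dx1a_c", {"dx1a_c": -1}, subsystem="Decoy"),
        ]
    return MetabolicModel(
        id=f"toy_template_{size}",
        metabolites=mets,
        reactions=rxns,
        objective_reaction="BIOMASS",
    )


def make_pyruvate_branch(seed: int = 0) -> MetabolicModel:
    """Minimal pyruvate-branch fixture with a forced glucose feed.

    Glucose uptake is pinned, so the pyruvate produced must exit either via
    lactate secretion or via a capacity-limited pyruvate-dehydrogenase step
    feeding the (growth-limiting) acetyl demand: raising the dehydrogenase
    flux necessarily lowers lactate secretion, a mass-balance-forced
    tradeoff.
    """

    mets = [
        Metabolite("glc_e", "glucose", "e"),
        Metabolite("pyr_c", "pyruvate", "c"),
        Metabolite("lac_c", "lactate", "c"),
        Metabolite("lac_e", "lactate", "e"),
        Metabolite("acc_c", "acetyl unit", "c"),
        Metabolite("bm_c", "biomass precursor", "c"),
    ]
    rxns = [
        _rxn("EX_glc_D_e", {"glc_e": -1}, lb=-10.0, ub=-10.0,
             subsystem="Exchange"),
        _rxn("GLY", {"glc_e": -1, "pyr_c": 2}, gpr="g_GLY",
             subsystem="Glycolysis"),
        _rxn("PDH", {"pyr_c": -1, "acc_c": 1}, gpr="g_PDH", ub=3.0,
             subsystem="Pyruvate metabolism"),
        _rxn("LDH", {"pyr_c": -1, "lac_c": 1}, gpr="g_LDH",
             subsystem="Fermentation"),
        _rxn("LACt", {"lac_c": -1, "lac_e": 1}, subsystem="Transport"),
        _rxn("EX_lac_L_e", {"lac_e": -1}, lb=0.0, subsystem="Exchange"),
        _rxn("BMS", {"acc_c": -1, "bm_c": 1}, subsystem="Biomass"),
        _rxn("BIOMASS", {"bm_c": -1}, subsystem="Biomass"),
    ]
    return MetabolicModel(
        id="pyruvate_branch",
        metabolites=mets,
        reactions=rxns,
        objective_reaction="BIOMASS",
    )


def default_media() -> Dict[str, MediaSpec]:
    """Media per cell type: the naive medium carries fatty acids, the
    effector medium does not (and allows more glucose)."""

    return {
        "naive": MediaSpec(
            uptake_bounds={
                "EX_glc_D_e": 5.0,
                "EX_gln_L_e": 1.0,
                "EX_fa_e": 5.0,
                "EX_leu_L_e": 2.0,
            }
        ),
        "effector": MediaSpec(
            uptake_bounds={
                "EX_glc_D_e": 10.0,
                "EX_gln_L_e": 1.0,
                "EX_leu_L_e": 2.0,
            }
        ),
    }


def default_profiles(template: MetabolicModel) -> Dict[str, Dict[str, float]]:
    """Gene activity probabilities per cell type.

    The naive profile runs fatty-acid uptake/oxidation and lacks de novo
    lipogenesis; the effector profile is the reverse. Shared central carbon
    genes are active in both. Decoy genes are active everywhere (their
    reactions simply never carry useful flux).
    """

    p_on, p_off = 0.95, 0.05
    naive_off = {"g_ACACA", "g_FASN", "g_GLUT3", "g_LDHB"}
    effector_off = {"g_CD36", "g_CPT1A", "g_ACSL3"}
    profiles: Dict[str, Dict[str, float]] = {"naive": {}, "effector": {}}
    for gene in sorted(template.genes):
        profiles["naive"][gene] = p_off if gene in naive_off else p_on
        profiles["effector"][gene] = p_off if gene in effector_off else p_on
    return profiles


def simulate_omics(
    template: MetabolicModel,
    profile: Dict[str, float],
    n_samples: int = 12,
    flip_noise: float = 0.03,
    dropout: float = 0.1,
    seed: int = 0,
) -> Tuple[PresenceMatrix, PresenceMatrix, AbundanceTable]:
    """Draw transcriptomic and proteomic layers for one cell profile.

    Each sample's call is the profile Bernoulli draw flipped with probability
    ``flip_noise``; the detection mask has independent ``dropout``. Proteomic
    abundances are log-normal with a higher location for active genes, so
    active genes concentrate in the top abundance quartile.
    """

    if not 0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    genes = sorted(template.genes)
    p = np.array([profile.get(g, 0.5) for g in genes])[:, None]

    def layer(n: int, tag: str) -> PresenceMatrix:
        base = rng.random((len(genes), n)) < p
        flip = rng.random((len(genes), n)) < flip_noise
        detected = rng.random((len(genes), n)) >= dropout
        calls = (base ^ flip) & detected
        cols = [f"{tag}_s{i + 1}" for i in range(n)]
        return PresenceMatrix(
            calls=pd.DataFrame(calls.astype(int), index=genes, columns=cols),
            detected=pd.DataFrame(detected.astype(int), index=genes, columns=cols),
        )

    trans = layer(n_samples, "tr")
    n_prot = max(3, n_samples // 3)
    prot = layer(n_prot, "pr")
    active_now = rng.random((len(genes), n_prot)) < p
    log_abund = np.where(active_now, 3.0, 0.0) + rng.normal(0, 0.8,
                                                            (len(genes), n_prot))
    abund = AbundanceTable(
        abundances=pd.DataFrame(
            np.exp(log_abund), index=genes,
            columns=[f"pr_s{i + 1}" for i in range(n_prot)],
        )
    )
    return trans, prot, abund


def simulate_disease(
    template: MetabolicModel,
    planted_target: str = PLANTED_TARGET,
    seed: int = 0,
    disease: str = "synthetic_disease",
    decoy_proportion: float = 0.5,
    moma_variant: str = "quadratic",
) -> Tuple[DEGTable, dict]:
    """Plant a disease signature that the target's knockout reverses.

    The perturbation machinery itself is run during generation: upregulated
    DEGs are drawn from genes all of whose reactions decrease in flux under
    the planted knockout, downregulated DEGs from genes all of whose
    reactions increase, and decoys (default half of the table) from genes
    whose reactions are unchanged. Fold changes and adjusted p-values are
    populated to pass the DEG filters.
    """

    if planted_target not in template.genes:
        raise ValueError(f"planted target {planted_target!r} not in template")
    if not disabled_reactions_for_gene(template, planted_target):
        raise ValueError(f"planted target {planted_target!r} is a silent knockout")
    rng = np.random.default_rng(seed)
    v_wt = fba(template)
    ko = gene_knockout(template, planted_target, v_wt, moma_variant=moma_variant)
    changes = classify_flux_changes(v_wt, ko.v_ko)
    down_rxns = changes.reactions_in_class("down")
    up_rxns = changes.reactions_in_class("up")

    def candidate_genes(wanted: Set[str], forbidden: Set[str]) -> List[str]:
        out = []
        for gene in sorted(template.genes - {planted_target}):
            rxns = {r.id for r in template.reactions if gene in r.gpr.genes}
            if rxns & wanted and not rxns & forbidden:
                out.append(gene)
        return out

    up_degs = candidate_genes(down_rxns, up_rxns)
    down_degs = candidate_genes(up_rxns, down_rxns)
    unchanged_pool = candidate_genes(
        {r.id for r in template.reactions} - down_rxns - up_rxns,
        down_rxns | up_rxns,
    )
    n_signal = len(up_degs) + len(down_degs)
    n_decoy = int(round(n_signal * decoy_proportion / (1 - decoy_proportion)))
    decoys = list(
        rng.choice(unchanged_pool, size=min(n_decoy, len(unchanged_pool)),
                   replace=False)
    )
    rows = []
    for gene in up_degs:
        rows.append((gene, float(rng.uniform(1.2, 3.0)), "up"))
    for gene in down_degs:
        rows.append((gene, float(-rng.uniform(1.2, 3.0)), "down"))
    for gene in decoys:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        rows.append((gene, float(sign * rng.uniform(1.2, 3.0)),
                     "up" if sign > 0 else "down"))
    table = pd.DataFrame(rows, columns=["gene_id", "log2fc", "direction"])
    table["p_adj"] = rng.uniform(1e-4, 0.01, size=len(table))
    table = table.set_index("gene_id")
    truth = {
        "planted_target": planted_target,
        "up_degs": up_degs,
        "down_degs": down_degs,
        "decoys": sorted(str(d) for d in decoys),
        "down_reactions": sorted(down_rxns),
        "up_reactions": sorted(up_rxns),
    }
    return (
        DEGTable(table=table, disease=disease, fc_cutoff=2.0, p_cutoff=0.05),
        truth,
    )


def simulate_annotations(
    template: MetabolicModel,
    coverage: float = 0.8,
    seed: int = 0,
    essential_cutoff: float = 0.01,
) -> Tuple[List[DrugAnnotation], Set[str]]:
    """Fictitious drug annotations plus a brute-force essentiality reference.

    A random ``coverage`` fraction of template genes is annotated with
    made-up drugs (statuses cycling launched / phase / preclinical); a few
    extra withdrawn drugs are added to exercise the withdrawn filter. The
    essential-gene truth is computed by exhaustive single-gene FBA deletion.
    """

    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(template.genes)
    n_annot = max(1, int(round(coverage * len(genes))))
    chosen = sorted(rng.choice(genes, size=n_annot, replace=False))
    statuses = ["launched", "phase", "preclinical"]
    annotations = [
        DrugAnnotation(drug=f"drug_{i + 1:03d}", status=statuses[i % 3],
                       targets=[gene])
        for i, gene in enumerate(chosen)
    ]
    n_withdrawn = max(1, len(chosen) // 8)
    for i, gene in enumerate(rng.choice(genes, size=n_withdrawn, replace=False)):
        annotations.append(
            DrugAnnotation(drug=f"withdrawn_{i + 1:03d}", status="withdrawn",
                           targets=[str(gene)])
        )
    wt = fba(template)
    essential: Set[str] = set()
    for gene in genes:
        disabled = disabled_reactions_for_gene(template, gene)
        if not disabled:
            continue
        work = template.copy()
        for rxn_id in disabled:
            rxn = work.reaction(rxn_id)
            rxn.lower_bound = rxn.upper_bound = 0.0
        try:
            growth = fba(work).objective_value
        except Exception:
            growth = 0.0
        if growth < essential_cutoff * wt.objective_value:
            essential.add(gene)
    return annotations, essential


@dataclass
class SyntheticScenario:
    """A complete in-memory study: template, profiles, omics, disease, drugs."""

    seed: int
    template: MetabolicModel
    media: Dict[str, MediaSpec]
    cell_profiles: Dict[str, Dict[str, float]]
    omics: Dict[str, Tuple[PresenceMatrix, PresenceMatrix, AbundanceTable]]
    planted_target: str
    deg_truth: DEGTable
    truth: dict
    drug_annotations: List[DrugAnnotation]
    essential_truth: Set[str]


def make_scenario(
    seed: int = 0,
    size: str = "small",
    n_samples: int = 12,
    flip_noise: float = 0.03,
    dropout: float = 0.1,
    coverage: float = 0.8,
    planted_target: str = PLANTED_TARGET,
    moma_variant: str = "quadratic",
) -> SyntheticScenario:
    """Generate one full synthetic study; every draw derives from ``seed``."""

    template = make_toy_template(seed=seed, size=size)
    media = default_media()
    profiles = default_profiles(template)
    omics = {
        cell: simulate_omics(
            template, profiles[cell], n_samples=n_samples,
            flip_noise=flip_noise, dropout=dropout,
            seed=seed * 97 + 11 * (i + 1),
        )
        for i, cell in enumerate(CELL_TYPES)
    }
    degs, truth = simulate_disease(
        template, planted_target=planted_target, seed=seed * 97 + 101,
        moma_variant=moma_variant,
    )
    annotations, essential = simulate_annotations(
        template, coverage=coverage, seed=seed * 97 + 211
    )
    # the screen must include the planted target: annotate it if coverage
    # happened to miss it
    if all(planted_target not in a.targets for a in annotations):
        annotations.append(
            DrugAnnotation(drug="drug_planted", status="launched",
                           targets=[planted_target])
        )
    return SyntheticScenario(
        seed=seed,
        template=template,
        media=media,
        cell_profiles=profiles,
        omics=omics,
        planted_target=planted_target,
        deg_truth=degs,
        truth=truth,
        drug_annotations=annotations,
        essential_truth=essential,
    )


def write_scenario(scenario: SyntheticScenario, out_dir) -> None:
    """Materialize a scenario directory: model JSON, omics/DEG/annotation
    TSVs, and a truth JSON."""

    from pathlib import Path

    from .network import write_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_model(scenario.template, out / "template.json")
    for cell, (trans, prot, abund) in scenario.omics.items():
        trans.calls.to_csv(out / f"{cell}_trans_calls.tsv", sep="\t")
        trans.detected.to_csv(out / f"{cell}_trans_detected.tsv", sep="\t")
        prot.calls.to_csv(out / f"{cell}_prot_calls.tsv", sep="\t")
        prot.detected.to_csv(out / f"{cell}_prot_detected.tsv", sep="\t")
        abund.abundances.to_csv(out / f"{cell}_prot_abundance.tsv", sep="\t")
    scenario.deg_truth.to_tsv(out / "degs.tsv")
    pd.DataFrame(
        [
            {"drug": a.drug, "status": a.status, "targets": "|".join(a.targets)}
            for a in scenario.drug_annotations
        ]
    ).to_csv(out / "annotations.tsv", sep="\t", index=False)
    media_dump = {
        cell: {"uptake_bounds": spec.uptake_bounds,
               "free_metabolites": sorted(spec.free_metabolites)}
        for cell, spec in scenario.media.items()
    }
    with open(out / "media.json", "w") as fh:
        json.dump(media_dump, fh, indent=1, sort_keys=True)
    truth = dict(scenario.truth)
    truth["essential_truth"] = sorted(scenario.essential_truth)
    truth["seed"] = scenario.seed
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
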