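"""End-to-end pipeline: integrate omics, build cell-type models, screen
drug-target knockouts, score perturbation effects, rank and select targets.

Each stage is a plain function over the typed objects of the other modules;
``run_pipeline`` strings them together for one disease across all cell-type
models and (optionally) writes every stage artifact into a run directory so
identical configs and seeds reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd

from .config import PipelineConfig
from .gimme import GimmeConfig, build_cell_model
from .network import MediaSpec, MetabolicModel, write_model
from .omics import (
    AbundanceTable,
    ActivityCalls,
    PresenceMatrix,
    discretize_calls,
    integrate_omics,
)
from .perturbation import (
    KnockoutResult,
    classify_flux_changes,
    filter_effective_targets,
    gene_knockout,
    map_drug_targets,
)
from .scoring import (
    DEGTable,
    PESRecord,
    aggregate_and_select,
    count_deg_flux_changes,
    pes,
    rank_pes,
    zscore_ranks,
)
from .solvers import fba
from .synth import SyntheticScenario

logger = logging.getLogger("fluxtarget")

__all__ = ["PipelineResult", "integrate_cell_omics", "screen_targets",
           "score_model_disease", "run_pipeline"]


@dataclass
class PipelineResult:
    """All per-stage artifacts of one pipeline run."""

    calls: Dict[str, ActivityCalls]
    models: Dict[str, MetabolicModel]
    build_reports: Dict[str, dict]
    knockouts: Dict[str, Dict[str, KnockoutResult]]
    effective_targets: Dict[str, Set[str]]
    pes_records: List[PESRecord]
    per_model_z: Dict[str, pd.Series]
    ranking: pd.DataFrame
    selected: List[str]


def integrate_cell_omics(
    trans: PresenceMatrix,
    prot: PresenceMatrix,
    abundance: AbundanceTable,
    config: PipelineConfig,
) -> ActivityCalls:
    """Discretize both layers and merge them into tiered activity calls."""

    trans_calls = discretize_calls(trans, threshold=config.discretization_threshold)
    prot_calls = discretize_calls(prot, threshold=config.discretization_threshold)
    return integrate_omics(
        trans_calls,
        prot_calls,
        prot_quantile=abundance.quantiles(),
        trans_support_cutoff=config.trans_support_cutoff,
        prot_quantile_cutoff=config.prot_quantile_cutoff,
    )


def screen_targets(
    model: MetabolicModel,
    target_genes: Set[str],
    config: PipelineConfig,
) -> Tuple[Dict[str, KnockoutResult], Set[str]]:
    """Knock out every mapped target gene; return results and the effective
    subset (those disabling at least one reaction)."""

    v_wt = fba(model)
    knockouts = {
        gene: gene_knockout(model, gene, v_wt, moma_variant=config.moma_variant)
        for gene in sorted(target_genes & model.genes)
    }
    effective = filter_effective_targets(knockouts.values())
    n_silent = len(knockouts) - len(effective)
    if n_silent:
        logger.warning("%s: %d silent knockout(s) excluded from scoring",
                       model.id, n_silent)
    return knockouts, effective


def score_model_disease(
    model: MetabolicModel,
    knockouts: Dict[str, KnockoutResult],
    effective: Set[str],
    degs: DEGTable,
    config: PipelineConfig,
    disease: str,
) -> List[PESRecord]:
    """PES per effective target for one (model, disease) pair."""

    v_wt = fba(model)
    records = []
    for gene in sorted(effective):
        changes = classify_flux_changes(
            v_wt, knockouts[gene].v_ko,
            rel_tol=config.rel_tol, abs_tol=config.abs_tol,
        )
        counts = count_deg_flux_changes(changes, degs, model)
        records.append(
            PESRecord(gene=gene, model_id=model.id, disease=disease,
                      counts=counts, pes=pes(counts))
        )
    return records


def run_pipeline(
    scenario: SyntheticScenario,
    config: Optional[PipelineConfig] = None,
    out_dir=None,
) -> PipelineResult:
    """Integrate -> build per cell type -> knockout screen -> score ->
    rank and select, for the scenario's disease."""

    config = config or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    gimme_cfg = GimmeConfig(
        biomass_fraction=config.gimme_fraction,
        inactive_penalty=config.inactive_penalty,
        tolerance=config.tol,
    )
    calls: Dict[str, ActivityCalls] = {}
    models: Dict[str, MetabolicModel] = {}
    reports: Dict[str, dict] = {}
    knockouts: Dict[str, Dict[str, KnockoutResult]] = {}
    effective: Dict[str, Set[str]] = {}
    all_records: List[PESRecord] = []
    per_model_z: Dict[str, pd.Series] = {}
    disease = scenario.deg_truth.disease or "disease"

    for cell, (trans, prot, abund) in scenario.omics.items():
        cell_calls = integrate_cell_omics(trans, prot, abund, config)
        calls[cell] = cell_calls
        model, report = build_cell_model(
            scenario.template, cell_calls, scenario.media[cell],
            tasks=None, config=gimme_cfg,
        )
        model.id = f"{scenario.template.id}_{cell}"
        models[cell] = model
        reports[cell] = report

        target_map = map_drug_targets(scenario.drug_annotations, model)
        kos, eff = screen_targets(model, set(target_map), config)
        knockouts[cell] = kos
        effective[cell] = eff
        records = score_model_disease(model, kos, eff, scenario.deg_truth,
                                      config, disease)
        all_records.extend(records)
        ranks = rank_pes({r.gene: r.pes for r in records})
        per_model_z[cell] = zscore_ranks(ranks, ddof=config.zscore_ddof)["z"]

        if out is not None:
            write_model(model, out / f"model_{cell}.json")
            with open(out / f"build_report_{cell}.json", "w") as fh:
                json.dump(report, fh, indent=1, sort_keys=True)
            cell_calls.to_tsv(out / f"activity_{cell}.tsv")

    ranking = aggregate_and_select(
        per_model_z,
        cutoff=config.aggregate_cutoff,
        restandardize=config.restandardize_aggregate,
        ddof=config.zscore_ddof,
    )
    selected = list(ranking.index[ranking["selected"]])

    if out is not None:
        pes_frame = pd.DataFrame(
            [
                {
                    "disease": r.disease, "model": r.model_id, "gene": r.gene,
                    "up_dec": r.counts.up_dec, "up_inc": r.counts.up_inc,
                    "up_unc": r.counts.up_unc, "down_dec": r.counts.down_dec,
                    "down_inc": r.counts.down_inc, "down_unc": r.counts.down_unc,
                    "pes": r.pes,
                }
                for r in all_records
            ]
        )
        pes_frame.to_csv(out / "pes_records.tsv", sep="\t", index=False)
        ranking.to_csv(out / "ranking.tsv", sep="\t")
        provenance = {
            "seed": scenario.seed,
            "disease": disease,
            "config_sha256": hashlib.sha256(
                json.dumps(config.__dict__, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "n_selected": len(selected),
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True)

    return PipelineResult(
        calls=calls,
        models=models,
        build_reports=reports,
        knockouts=knockouts,
        effective_targets=effective,
        pes_records=all_records,
        per_model_z=per_model_z,
        ranking=ranking,
        selected=selected,
    )
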