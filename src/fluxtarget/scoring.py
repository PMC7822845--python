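"""Perturbation Effect Score (PES) and drug-target prioritization.

For a candidate target gene knocked out in one cell-type model, reactions
controlled by disease-upregulated genes are counted by flux-change class
(UpDec / UpInc / UpUnc), likewise for downregulated genes (DownDec / DownInc
/ DownUnc), and

    PES = (UpDec - UpInc) / (UpDec + UpInc + UpUnc)
        + (DownInc - DownDec) / (DownInc + DownDec + DownUnc)

so PES lies in [-2, 2] and is maximal when the knockout reverses every
DEG-controlled flux. Per model and disease, PES values are ranked (rank 1 =
highest PES), ranks are standardized to Z-scores, summed across cell-type
models, and targets with a sufficiently negative aggregated Z-score are
selected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import MetabolicModel, reactions_of_gene
from .perturbation import (
    CLASS_DOWN,
    CLASS_UNCHANGED,
    CLASS_UP,
    FluxChangeTable,
)

__all__ = [
    "DEGTable",
    "PESCounts",
    "PESRecord",
    "load_degs",
    "count_deg_flux_changes",
    "pes",
    "rank_pes",
    "zscore_ranks",
    "aggregate_and_select",
    "pathway_enrichment",
]

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"


@dataclass
class DEGTable:
    """Filtered differentially expressed genes for one disease.

    ``table`` columns: gene_id (index), log2fc, direction, p_adj. All rows
    satisfy the adjusted-p and fold-change cutoffs recorded in
    ``fc_cutoff``/``p_cutoff``.
    """

    table: pd.DataFrame
    disease: str = ""
    fc_cutoff: float = 2.0
    p_cutoff: float = 0.05

    @property
    def up_genes(self) -> Set[str]:
        return set(self.table.index[self.table["direction"] == DIRECTION_UP])

    @property
    def down_genes(self) -> Set[str]:
        return set(self.table.index[self.table["direction"] == DIRECTION_DOWN])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def load_degs(
    source,
    disease: str = "",
    metabolic_genes: Optional[Set[str]] = None,
    primary_fc_cutoff: float = 2.0,
    fallback_fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    min_metabolic_degs: int = 10,
) -> DEGTable:
    """Load and filter a DEG table (TSV or DataFrame: gene_id, log2fc,
    direction, p_adj).

    Rows must pass ``p_adj < p_cutoff`` and ``|fold change| >= 2``; if that
    leaves fewer than ``min_metabolic_degs`` metabolic DEGs (intersection
    with ``metabolic_genes`` when given), the 1.5-fold fallback cutoff is
    applied instead. The cutoff actually used is recorded on the result.
    """

    if isinstance(source, pd.DataFrame):
        df = source.copy()
        if df.index.name != "gene_id":
            df = df.set_index("gene_id")
    else:
        df = pd.read_csv(source, sep="\t")
        missing = {"gene_id", "log2fc", "p_adj"} - set(df.columns)
        if missing:
            raise ValueError(f"DEG table missing columns: {sorted(missing)}")
        df = df.set_index("gene_id")
    if "direction" not in df.columns:
        df["direction"] = np.where(df["log2fc"] >= 0, DIRECTION_UP, DIRECTION_DOWN)

    def apply_cutoff(fc: float) -> pd.DataFrame:
        keep = (df["p_adj"] < p_cutoff) & (df["log2fc"].abs() >= math.log2(fc))
        return df[keep]

    chosen = primary_fc_cutoff
    filtered = apply_cutoff(primary_fc_cutoff)
    universe = metabolic_genes if metabolic_genes is not None else set(df.index)
    if len(set(filtered.index) & universe) < min_metabolic_degs:
        chosen = fallback_fc_cutoff
        filtered = apply_cutoff(fallback_fc_cutoff)
    return DEGTable(
        table=filtered, disease=disease, fc_cutoff=chosen, p_cutoff=p_cutoff
    )


@dataclass(frozen=True)
class PESCounts:
    """The six reaction counts entering the PES."""

    up_dec: int = 0
    up_inc: int = 0
    up_unc: int = 0
    down_dec: int = 0
    down_inc: int = 0
    down_unc: int = 0

    def __post_init__(self) -> None:
        for name in ("up_dec", "up_inc", "up_unc", "down_dec", "down_inc", "down_unc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class PESRecord:
    gene: str
    model_id: str
    disease: str
    counts: PESCounts
    pes: float


def count_deg_flux_changes(
    flux_table: FluxChangeTable,
    degs: DEGTable,
    model: MetabolicModel,
) -> PESCounts:
    """Count DEG-controlled reactions per flux-change class.

    The up-group is the set of distinct reactions whose GPR contains at least
    one upregulated DEG (union semantics: a reaction regulated by several
    same-direction DEGs counts once), partitioned into decreased / increased
    / unchanged; likewise for the down-group. A reaction regulated by both an
    up- and a down-DEG contributes to both groups.
    """

    def group_reactions(deg_genes: Set[str]) -> Set[str]:
        out: Set[str] = set()
        for gene in deg_genes & model.genes:
            out |= reactions_of_gene(model, gene)
        return out & set(flux_table.table.index)

    def partition(rxns: Set[str]) -> Tuple[int, int, int]:
        dec = sum(1 for r in rxns if flux_table.class_of(r) == CLASS_DOWN)
        inc = sum(1 for r in rxns if flux_table.class_of(r) == CLASS_UP)
        unc = sum(1 for r in rxns if flux_table.class_of(r) == CLASS_UNCHANGED)
        return dec, inc, unc

    up_dec, up_inc, up_unc = partition(group_reactions(degs.up_genes))
    down_dec, down_inc, down_unc = partition(group_reactions(degs.down_genes))
    return PESCounts(up_dec, up_inc, up_unc, down_dec, down_inc, down_unc)


def pes(counts: PESCounts) -> float:
    """The perturbation effect score; a zero-denominator term contributes 0."""

    up_total = counts.up_dec + counts.up_inc + counts.up_unc
    down_total = counts.down_dec + counts.down_inc + counts.down_unc
    score = 0.0
    if up_total > 0:
        score += (counts.up_dec - counts.up_inc) / up_total
    if down_total > 0:
        score += (counts.down_inc - counts.down_dec) / down_total
    return score


def rank_pes(scores: Mapping[str, float]) -> Dict[str, float]:
    """Rank genes by PES: rank 1 = highest score, ties get the average rank."""

    if not scores:
        raise ValueError("no PES records to rank")
    genes = sorted(scores)
    values = np.array([scores[g] for g in genes])
    ranks = stats.rankdata(-values, method="average")
    return {g: float(r) for g, r in zip(genes, ranks)}


def zscore_ranks(ranks: Mapping[str, float], ddof: int = 1) -> pd.DataFrame:
    """Standardize PES ranks to Z-scores: z = (x - mean) / sd.

    Sample (n-1) standard deviation by default (``ddof=0`` for population).
    If every rank is tied the Z-scores are all 0 and a warning is emitted.
    """

    genes = sorted(ranks)
    x = np.array([ranks[g] for g in genes], dtype=float)
    mu = x.mean()
    sigma = x.std(ddof=ddof) if len(x) > ddof else 0.0
    if sigma == 0.0:
        warnings.warn("all PES ranks tied; Z-scores set to 0", stacklevel=2)
        z = np.zeros_like(x)
    else:
        z = (x - mu) / sigma
    return pd.DataFrame({"rank": x, "z": z}, index=pd.Index(genes, name="gene"))


def aggregate_and_select(
    per_model_z: Mapping[str, pd.Series],
    cutoff: float = -1.0,
    restandardize: bool = True,
    ddof: int = 1,
) -> pd.DataFrame:
    """Sum per-model Z-scores and select targets below the cutoff.

    A gene missing from any model is excluded (with a warning). With
    ``restandardize`` (default) the aggregated sums are re-standardized so
    the -1 cutoff reads "one standard deviation below the mean aggregated
    Z-score"; ``restandardize=False`` applies the cutoff to the raw sums.
    Output rows are ordered by ascending aggregate (best target first), with
    columns ``z_<model>``, aggregate, aggregate_z, rank, selected.
    """

    z_frame = pd.DataFrame(
        {model_id: z for model_id, z in per_model_z.items()}
    )
    complete = z_frame.dropna()
    dropped = sorted(set(z_frame.index) - set(complete.index))
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene(s) missing a Z-score in some model, excluded: "
            f"{dropped[:10]}",
            stacklevel=2,
        )
    aggregate = complete.sum(axis=1)
    if restandardize and len(aggregate) > ddof and aggregate.std(ddof=ddof) > 0:
        agg_z = (aggregate - aggregate.mean()) / aggregate.std(ddof=ddof)
    else:
        agg_z = aggregate.copy()
    out = complete.rename(columns=lambda m: f"z_{m}")
    out["aggregate"] = aggregate
    out["aggregate_z"] = agg_z
    out["selected"] = agg_z <= cutoff
    out = out.sort_values("aggregate")
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "gene"
    return out


def pathway_enrichment(
    gene_set: Set[str],
    background: Set[str],
    pathway_map: Mapping[str, Set[str]],
    p_cutoff: float = 0.05,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact (hypergeometric tail) enrichment per pathway.

    fold_enrichment = (k/n) / (K/N) with k = hits in the pathway, n = size of
    the gene set, K = pathway genes in the background, N = background size.
    P-values are Benjamini-Hochberg corrected across pathways; a pathway is
    significant iff p < 0.05 and FDR < 5%.
    """

    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of the background universe")
    N = len(background)
    n = len(gene_set)
    rows = []
    for pathway, members in sorted(pathway_map.items()):
        K = len(members & background)
        if K == 0:
            warnings.warn(f"pathway {pathway} has no background genes; skipped",
                          stacklevel=2)
            continue
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append((pathway, k, n, K, N, fold, p))
    out = pd.DataFrame(
        rows, columns=["pathway", "k", "n", "K", "N", "fold_enrichment", "p"]
    ).set_index("pathway")
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = (out["p"] < p_cutoff) & (out["fdr"] < fdr_cutoff)
    else:
        out["fdr"] = []
        out["significant"] = []
    return out
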