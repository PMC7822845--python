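"""Discretization and consensus integration of transcriptomics/proteomics.

Expression is reduced to binary gene activity: a gene is active in one
dataset when it is expressed in more than half of the samples in which its
probe was detected. Transcriptomic and proteomic activity calls are then
merged into confidence tiers:

* ``high`` — active in both omics layers;
* ``moderate_transcriptomic`` — active only in transcriptomics, but in at
  least 90% of samples;
* ``moderate_proteomic`` — active only in proteomics, with abundance ranked
  in the top quartile;
* everything else is inactive.

The asymmetric rescue rules trade a few false positives for far fewer false
negatives in sparsely sampled proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

__all__ = [
    "PresenceMatrix",
    "AbundanceTable",
    "ActivityCalls",
    "discretize_calls",
    "combine_datasets",
    "integrate_omics",
]

TIER_HIGH = "high"
TIER_MOD_TRANS = "moderate_transcriptomic"
TIER_MOD_PROT = "moderate_proteomic"
TIER_NONE = "none"


@dataclass
class PresenceMatrix:
    """Binary expression calls with a parallel probe-detection mask.

    ``calls`` and ``detected`` are genes x samples 0/1 frames with identical
    index/columns; a call of 1 requires detection 1.
    """

    calls: pd.DataFrame
    detected: pd.DataFrame
    dataset_id: str = ""
    cell_type: str = ""

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.detected.index) or not (
            self.calls.columns.equals(self.detected.columns)
        ):
            raise ValueError("calls and detected must share index and columns")
        bad = (self.calls.to_numpy() > self.detected.to_numpy()).any()
        if bad:
            raise ValueError("expression call 1 where probe not detected")

    @classmethod
    def from_tsv(cls, calls_path, detected_path, dataset_id: str = "",
                 cell_type: str = "") -> "PresenceMatrix":
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        detected = pd.read_csv(detected_path, sep="\t", index_col=0)
        return cls(calls=calls, detected=detected, dataset_id=dataset_id,
                   cell_type=cell_type)


@dataclass
class AbundanceTable:
    """Proteomics abundances (genes x samples), ranked to quantiles per sample."""

    abundances: pd.DataFrame
    dataset_id: str = ""

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[1]

    def quantiles(self) -> pd.Series:
        """Per-gene abundance quantile in [0, 1].

        Ranks are computed within each sample (abundance scales differ across
        runs) and averaged across samples.
        """

        per_sample = self.abundances.rank(axis=0, pct=True)
        return per_sample.mean(axis=1)


@dataclass
class ActivityCalls:
    """Per-gene binary activity with confidence tier and sample support.

    ``table`` is indexed by gene id with columns ``active`` (bool), ``tier``
    (str) and ``support`` (fraction of samples, in [0, 1]). Genes whose probe
    was never detected are listed in ``undetermined`` and excluded from the
    table — absence of evidence is not evidence of inactivity.
    """

    table: pd.DataFrame
    undetermined: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        sup = self.table["support"].to_numpy(dtype=float)
        if len(sup) and (np.nanmin(sup) < 0 or np.nanmax(sup) > 1):
            raise ValueError("support must lie in [0, 1]")

    @property
    def active_genes(self) -> Set[str]:
        return set(self.table.index[self.table["active"]])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ActivityCalls":
        table = pd.read_csv(path, sep="\t", index_col="gene_id")
        table["active"] = table["active"].astype(bool)
        return cls(table=table)


def discretize_calls(matrix: PresenceMatrix, threshold: float = 0.5) -> ActivityCalls:
    """Binary per-gene activity from a presence matrix.

    A gene is active iff it is expressed in *more than* ``threshold`` of the
    samples in which its probe was detected (strict inequality, so 2-of-4 at
    the default 0.5 is inactive). Genes never detected are undetermined.
    """

    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if matrix.calls.size == 0:
        raise ValueError("empty presence matrix")
    n_pos = matrix.calls.sum(axis=1)
    n_det = matrix.detected.sum(axis=1)
    determined = n_det > 0
    support = (n_pos[determined] / n_det[determined]).astype(float)
    table = pd.DataFrame(
        {
            "active": support > threshold,
            "tier": TIER_NONE,
            "support": support,
        }
    )
    return ActivityCalls(table=table,
                         undetermined=set(matrix.calls.index[~determined]))


def combine_datasets(
    calls_list: Sequence[ActivityCalls], threshold: float = 0.5
) -> ActivityCalls:
    """Majority consensus of per-dataset activity calls for one cell type.

    A gene is active iff it is active in more than ``threshold`` of the
    datasets in which it was determined — the per-dataset majority prevents
    large datasets from dominating. The reported ``support`` is the mean of
    per-dataset sample supports, which downstream rescue rules read as the
    fraction of samples expressing the gene.
    """

    if not calls_list:
        raise ValueError("no datasets to combine")
    if len(calls_list) == 1:
        return calls_list[0]
    active = pd.concat([c.table["active"] for c in calls_list], axis=1)
    support = pd.concat([c.table["support"] for c in calls_list], axis=1)
    n_det = active.notna().sum(axis=1)
    n_act = active.fillna(False).sum(axis=1)
    determined = n_det > 0
    table = pd.DataFrame(
        {
            "active": (n_act[determined] / n_det[determined]) > threshold,
            "tier": TIER_NONE,
            "support": support.mean(axis=1, skipna=True)[determined],
        }
    )
    never = set().union(*(c.undetermined for c in calls_list)) - set(table.index)
    return ActivityCalls(table=table, undetermined=never)


def integrate_omics(
    trans: ActivityCalls,
    prot: ActivityCalls,
    trans_support: Optional[pd.Series] = None,
    prot_quantile: Optional[pd.Series] = None,
    trans_support_cutoff: float = 0.90,
    prot_quantile_cutoff: float = 0.75,
) -> ActivityCalls:
    """Merge transcriptomic and proteomic activity into confidence tiers.

    Parameters
    ----------
    trans_support
        Per-gene fraction of transcriptomics samples expressing the gene;
        defaults to ``trans.table["support"]``.
    prot_quantile
        Per-gene proteomics abundance quantile in [0, 1] (see
        :meth:`AbundanceTable.quantiles`); required for the proteomics-only
        rescue tier — genes without a quantile cannot be rescued.
    """

    if trans_support is None:
        trans_support = trans.table["support"]
    if prot_quantile is None:
        prot_quantile = pd.Series(dtype=float)

    genes = sorted(set(trans.table.index) | set(prot.table.index))
    t_active = trans.table["active"].reindex(genes).fillna(False)
    p_active = prot.table["active"].reindex(genes).fillna(False)
    t_sup = pd.Series(trans_support).reindex(genes)
    p_quant = pd.Series(prot_quantile).reindex(genes)

    rows = []
    for g in genes:
        ta, pa = bool(t_active[g]), bool(p_active[g])
        if ta and pa:
            active, tier = True, TIER_HIGH
        elif ta and not pa and float(t_sup.get(g) or 0.0) >= trans_support_cutoff:
            active, tier = True, TIER_MOD_TRANS
        elif pa and not ta and float(p_quant.get(g) or 0.0) >= prot_quantile_cutoff:
            active, tier = True, TIER_MOD_PROT
        else:
            active, tier = False, TIER_NONE
        support = t_sup.get(g)
        if support is None or pd.isna(support):
            support = prot.table["support"].get(g, np.nan)
        rows.append((g, active, tier, float(support) if pd.notna(support) else np.nan))

    table = pd.DataFrame(
        rows, columns=["gene_id", "active", "tier", "support"]
    ).set_index("gene_id")
    return ActivityCalls(
        table=table, undetermined=trans.undetermined & prot.undetermined
    )
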