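"""Pipeline configuration: every tunable threshold in one validated place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass
class PipelineConfig:
    """All pipeline thresholds with their documented defaults.

    Omics integration: a gene is active when expressed in more than
    ``discretization_threshold`` of detected samples; transcriptomics-only
    genes need sample support >= ``trans_support_cutoff``; proteomics-only
    genes need abundance quantile >= ``prot_quantile_cutoff`` (top quartile).

    Extraction: the context model must reach ``gimme_fraction`` of the
    template optimum. DEG filtering: adjusted p < ``p_cutoff`` with
    ``primary_fc_cutoff``-fold change, falling back to
    ``fallback_fc_cutoff``-fold when fewer than ``min_metabolic_degs``
    metabolic DEGs survive. Selection: aggregated rank Z-score <=
    ``aggregate_cutoff``.
    """

    # discretization / integration
    discretization_threshold: float = 0.5
    trans_support_cutoff: float = 0.90
    prot_quantile_cutoff: float = 0.75
    # extraction
    gimme_fraction: float = 0.9
    inactive_penalty: float = 1.0
    # numeric tolerances
    tol: float = 1e-6
    rel_tol: float = 0.05
    abs_tol: float = 1e-6
    # DEG filtering
    primary_fc_cutoff: float = 2.0
    fallback_fc_cutoff: float = 1.5
    p_cutoff: float = 0.05
    min_metabolic_degs: int = 10
    # essentiality
    essential_cutoff: float = 0.01
    reduced_cutoff: float = 0.5
    # scoring / selection
    aggregate_cutoff: float = -1.0
    restandardize_aggregate: bool = True
    zscore_ddof: int = 1
    # solver
    moma_variant: str = "quadratic"
    # reproducibility
    seed: int = 0
    # manual curation hook: reaction id -> [lower_bound, upper_bound]
    directionality_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (0 < self.discretization_threshold <= 1, "discretization_threshold in (0,1]"),
            (0 <= self.trans_support_cutoff <= 1, "trans_support_cutoff in [0,1]"),
            (0 <= self.prot_quantile_cutoff <= 1, "prot_quantile_cutoff in [0,1]"),
            (0 < self.gimme_fraction <= 1, "gimme_fraction in (0,1]"),
            (self.inactive_penalty > 0, "inactive_penalty > 0"),
            (self.tol > 0 and self.abs_tol > 0, "tolerances > 0"),
            (0 <= self.rel_tol < 1, "rel_tol in [0,1)"),
            (self.primary_fc_cutoff >= self.fallback_fc_cutoff > 1,
             "fold-change cutoffs > 1 with primary >= fallback"),
            (0 < self.p_cutoff < 1, "p_cutoff in (0,1)"),
            (self.min_metabolic_degs >= 0, "min_metabolic_degs >= 0"),
            (0 <= self.essential_cutoff < self.reduced_cutoff <= 1,
             "essential_cutoff < reduced_cutoff in [0,1]"),
            (self.moma_variant in ("quadratic", "linear"),
             "moma_variant quadratic|linear"),
            (self.zscore_ddof in (0, 1), "zscore_ddof 0|1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(f"invalid configuration: require {msg}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
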