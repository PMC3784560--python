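"""Run configuration: one place for every tunable threshold.

A :class:`RunConfig` collects the input file paths and all numeric settings
used by the pipeline stages and can be round-tripped through YAML; the CLI
serialises the resolved configuration next to its outputs for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .annotations import EnrichmentThresholds
from .bayes import DEFAULT_R_STAR, BayesConfig, ScalingConfig
from .cohort import FilterConfig
from .pipeline import ScoreConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All inputs and tunables of a pipeline run."""

    # input paths (GMT files keyed by system name)
    gmt_files: dict[str, str] = field(default_factory=dict)
    expression_file: str | None = None
    network_file: str | None = None
    training_file: str | None = None
    cnv_file: str | None = None
    cnv_dialect: str = "closed"
    gene_models_file: str | None = None
    output_dir: str = "phenoprior_out"
    seed: int = 0

    # enrichment (per-system overrides allowed)
    max_p: float = 0.01
    min_odds_ratio: float = 2.0
    min_training: int = 2
    per_system_thresholds: dict[str, dict[str, float]] = field(default_factory=dict)

    # expression contrast
    expression_q: float = 0.1
    expression_min_side: int = 3

    # interaction network
    ppi_max_len: int = 6

    # Bayes model
    variance_multiple: float | None = None  # None -> 1/n_bg (cohort-matched)
    pseudo_rate_fraction: float = 0.25
    scaling_kappa: float | None = None  # None -> calibrated from the anchor
    scaling_r_star: float = DEFAULT_R_STAR
    scaling_anchor_score: float = 1.0
    scaling_anchor_rate: float = 1.0 / 2940.0
    scaling_anchor_value: float = 4.5

    # call filters
    max_interval_bp: int = 15_000_000
    min_probes: int = 4
    del_log2_max: float = -0.3
    dup_log2_min: float = 0.21

    # cohort sizes (subjects without calls still count)
    n_case: int | None = None
    n_background: int | None = None

    def score_config(self) -> ScoreConfig:
        thresholds = {
            name: EnrichmentThresholds(
                max_p=vals.get("max_p", self.max_p),
                min_odds_ratio=vals.get("min_odds_ratio", self.min_odds_ratio),
                min_training=int(vals.get("min_training", self.min_training)),
            )
            for name, vals in self.per_system_thresholds.items()
        }
        default = EnrichmentThresholds(
            max_p=self.max_p,
            min_odds_ratio=self.min_odds_ratio,
            min_training=self.min_training,
        )
        for name in self.gmt_files:
            thresholds.setdefault(name, default)
        return ScoreConfig(
            thresholds=thresholds,
            expression_q=self.expression_q,
            expression_min_side=self.expression_min_side,
            ppi_max_len=self.ppi_max_len,
        )

    def bayes_config(self) -> BayesConfig:
        return BayesConfig(
            c=self.variance_multiple,
            pseudo_fraction=self.pseudo_rate_fraction,
            scaling=ScalingConfig(
                r_star=self.scaling_r_star,
                kappa=self.scaling_kappa,
                anchor_score=self.scaling_anchor_score,
                anchor_rate=self.scaling_anchor_rate,
                anchor_value=self.scaling_anchor_value,
            ),
        )

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            max_span_bp=self.max_interval_bp,
            min_probes=self.min_probes,
            del_log2_max=self.del_log2_max,
            dup_log2_min=self.dup_log2_min,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
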