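"""End-to-end composite pathogenicity scoring.

Ties the per-source features together: annotation match scores for each
category system, the expression contrast statistic, and the network
communicability sum, each converted to the standardised tail log-ratio
metric and averaged into the composite score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .annotations import (
    AnnotationSystem,
    EnrichmentThresholds,
    match_scores,
    select_enriched_categories,
)
from .expression import select_contrast_tissues, tstat_table
from .fusion import compose, standardize, tail_logratio_table
from .ppi import DEFAULT_MAX_LEN, communicability_to_training, sum_training_block

__all__ = ["KnowledgeBundle", "ScoreConfig", "score_genes"]


@dataclass
class KnowledgeBundle:
    """All knowledge-source inputs for one scoring run.

    ``genes`` is the master gene list over which scores are reported (the
    "all annotated genes" complement); sources may each cover only part of it.
    """

    systems: dict[str, AnnotationSystem]
    expression: pd.DataFrame  # genes x tissues
    network: nx.Graph
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate symbols in master gene list")


@dataclass
class ScoreConfig:
    """Tunables of the scoring pipeline (single source of truth)."""

    thresholds: dict[str, EnrichmentThresholds] = field(default_factory=dict)
    expression_q: float = 0.1
    expression_min_side: int = 3
    ppi_max_len: int = DEFAULT_MAX_LEN

    def thresholds_for(self, system: str) -> EnrichmentThresholds:
        return self.thresholds.get(system, EnrichmentThresholds())


def _standardize_or_missing(raw: pd.Series, training: set[str], name: str) -> pd.Series:
    """Tail log-ratio + z-standardisation; a degenerate feature becomes
    all-missing with a warning instead of aborting the run."""
    try:
        metric = tail_logratio_table(raw, training)
        return standardize(metric).rename(name)
    except ValueError as exc:
        warnings.warn(f"feature {name!r} degenerate ({exc}); treated as missing")
        return pd.Series(np.nan, index=raw.index, name=name)


def score_genes(
    bundle: KnowledgeBundle,
    training: Iterable[str],
    config: ScoreConfig | None = None,
) -> pd.DataFrame:
    """Composite pathogenicity scores for every gene in the bundle.

    Returns a DataFrame indexed by gene with one standardised column per
    knowledge source plus ``composite``.  Genes not covered by a source are
    missing (NaN) in that column; the composite averages available columns
    and is 0 when everything is missing.
    """
    config = config or ScoreConfig()
    training = set(training)
    index = pd.Index(bundle.genes, name="gene")
    columns: list[pd.Series] = []

    for name, system in bundle.systems.items():
        enriched = select_enriched_categories(
            system, training, config.thresholds_for(name)
        )
        raw = pd.Series(match_scores(bundle.genes, enriched, system), name=name)
        raw = raw.reindex(index)
        columns.append(_standardize_or_missing(raw, training, name))

    contrast = select_contrast_tissues(
        bundle.expression, training, q=config.expression_q,
        min_per_side=config.expression_min_side,
    )
    raw_expr = tstat_table(bundle.expression, contrast).reindex(index)
    columns.append(_standardize_or_missing(raw_expr, training, "expression"))

    raw_ppi = communicability_to_training(
        bundle.network, training, max_len=config.ppi_max_len
    ).reindex(index)
    columns.append(_standardize_or_missing(raw_ppi, training, "ppi"))

    table = pd.concat(columns, axis=1)
    table.index = index
    return compose(table)
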