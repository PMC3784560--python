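"""Synthetic study generator.

Generates every input the pipeline consumes -- category-based annotation
systems, a gene x tissue expression matrix, an interaction network, a
training gene list, gene models on a synthetic genome, and per-subject CNV
call tables -- with the statistical structure the method assumes: training
genes over-represented in designated categories, elevated in designated
tissues, preferentially interconnected in the network, and a subset of them
("risk genes") deleted at an elevated rate in case subjects only.

Three independent pseudo-random streams (knowledge, network, cohorts) are
spawned from the master seed, so regenerating one input does not perturb
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .pipeline import KnowledgeBundle
from .annotations import AnnotationSystem

__all__ = [
    "SimulationConfig",
    "null_config",
    "gene_models",
    "simulate_knowledge",
    "simulate_cohorts",
    "SimulatedStudy",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults define the study conditions used throughout the test suite."""

    seed: int = 0
    n_genes: int = 800
    n_training: int = 30

    # annotation systems
    systems: tuple[str, ...] = ("go", "mgi", "kegg", "mirna")
    n_categories: int = 40
    mean_category_size: int = 25
    n_enriched_categories: int = 8  # designated training-enriched per system
    training_odds_multiplier: float = 12.0  # membership-probability boost
    missing_fraction: float = 0.1  # genes absent from each knowledge source

    # expression
    n_tissues: int = 20
    n_elevated_tissues: int = 3
    expression_effect: float = 2.0  # additive shift of training genes
    expression_noise_sd: float = 1.0

    # interaction network
    edge_prob: float = 0.01
    training_edge_boost: float = 0.15  # extra edge probability among training

    # cohorts
    n_case: int = 2000
    n_background: int = 2000
    baseline_deletion_rate: float = 0.0005  # per subject per gene
    n_risk_genes: int = 5
    risk_multiplier: float = 20.0
    duplication_rate: float = 0.0002
    filter_fail_fraction: float = 0.1  # calls corrupted to violate one filter
    span_continue_prob: float = 0.4  # geometric extension to neighbour genes
    max_span_genes: int = 3

    # synthetic genome layout
    gene_length: int = 40_000
    gene_gap: int = 20_000

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_training <= 0:
            raise ValueError("counts must be positive")
        if self.n_training >= self.n_genes:
            raise ValueError("n_training must be smaller than n_genes")
        for p in (
            self.missing_fraction,
            self.edge_prob,
            self.training_edge_boost,
            self.filter_fail_fraction,
            self.span_continue_prob,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.training_odds_multiplier < 0 or self.risk_multiplier < 0:
            raise ValueError("multipliers must be nonnegative")
        if self.n_risk_genes > self.n_training:
            raise ValueError("risk genes are drawn from the training set")
        base_p = self.mean_category_size / self.n_genes
        if base_p * max(self.training_odds_multiplier, 1.0) > 1.0:
            raise ValueError("training membership boost exceeds probability budget")


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with no planted signal anywhere."""
    return SimulationConfig(
        seed=seed,
        training_odds_multiplier=1.0,
        expression_effect=0.0,
        training_edge_boost=0.0,
        risk_multiplier=1.0,
        **overrides,
    )


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    kn, net, coh = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(kn),
        np.random.default_rng(net),
        np.random.default_rng(coh),
    )


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def gene_models(config: SimulationConfig) -> pd.DataFrame:
    """Gene coordinates on a one-chromosome synthetic genome (1-based closed).

    Genes are evenly spaced with a configurable gap so that extended
    deletions span several adjacent genes.
    """
    pitch = config.gene_length + config.gene_gap
    starts = np.arange(config.n_genes) * pitch + 1
    return pd.DataFrame(
        {
            "gene": _gene_names(config.n_genes),
            "chrom": "chr1",
            "start": starts,
            "end": starts + config.gene_length - 1,
        }
    )


def _simulate_system(
    name: str,
    genes: list[str],
    training: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> AnnotationSystem:
    n = len(genes)
    keep = rng.random(n) >= config.missing_fraction
    universe = [g for g, k in zip(genes, keep) if k]
    uni_set = set(universe)
    base_p = config.mean_category_size / config.n_genes
    boost_p = min(0.95, base_p * config.training_odds_multiplier)
    train_u = [t for t in training if t in uni_set]
    categories: dict[str, set[str]] = {}
    for c in range(config.n_categories):
        size = max(5, int(rng.poisson(config.mean_category_size)))
        members = set(rng.choice(universe, size=min(size, len(universe)), replace=False))
        if c < config.n_enriched_categories:
            # designated categories recruit training genes at the boosted rate
            extra = [t for t in train_u if rng.random() < boost_p]
            members |= set(extra)
        if members and members != uni_set:
            categories[f"{name}_cat{c:03d}"] = members
    return AnnotationSystem.from_categories(name, categories, universe)


def _simulate_expression(
    genes: list[str],
    training: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    tissues = [f"T{j:02d}" for j in range(config.n_tissues)]
    values = rng.normal(5.0, config.expression_noise_sd, (len(genes), config.n_tissues))
    expr = pd.DataFrame(values, index=genes, columns=tissues)
    elevated = tissues[: config.n_elevated_tissues]
    expr.loc[expr.index.isin(training), elevated] += config.expression_effect
    keep = rng.random(len(genes)) >= config.missing_fraction
    return expr.loc[keep]


def _simulate_network(
    genes: list[str],
    training: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> nx.Graph:
    keep = rng.random(len(genes)) >= config.missing_fraction
    nodes = [g for g, k in zip(genes, keep) if k]
    pos = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    iu, ju = np.triu_indices(n, k=1)
    edge = rng.random(iu.size) < config.edge_prob
    train_idx = np.zeros(n, dtype=bool)
    for t in training:
        if t in pos:
            train_idx[pos[t]] = True
    both_training = train_idx[iu] & train_idx[ju]
    if config.training_edge_boost > 0:
        edge |= both_training & (rng.random(iu.size) < config.training_edge_boost)
    for i, j in zip(iu[edge], ju[edge]):
        graph.add_edge(nodes[i], nodes[j])
    return graph


def simulate_knowledge(
    config: SimulationConfig,
) -> tuple[KnowledgeBundle, list[str]]:
    """Knowledge-source inputs plus the training gene list.

    Same seed, same outputs, byte for byte.
    """
    rng_knowledge, rng_network, _ = _streams(config.seed)
    genes = _gene_names(config.n_genes)
    training = sorted(
        rng_knowledge.choice(genes, size=config.n_training, replace=False).tolist()
    )
    systems = {
        name: _simulate_system(name, genes, training, config, rng_knowledge)
        for name in config.systems
    }
    expression = _simulate_expression(genes, training, config, rng_knowledge)
    network = _simulate_network(genes, training, config, rng_network)
    bundle = KnowledgeBundle(
        systems=systems, expression=expression, network=network, genes=tuple(genes)
    )
    return bundle, training


def risk_genes(config: SimulationConfig, training: list[str]) -> list[str]:
    """Planted high-risk genes: the first ``n_risk_genes`` of the (sorted)
    training list, so the choice is deterministic given the training set."""
    return sorted(training)[: config.n_risk_genes]


def _corrupt_call(call: dict, rng: np.random.Generator) -> dict:
    """Make a call violate exactly one true-positive filter rule."""
    mode = rng.integers(0, 3)
    if mode == 0:
        call["n_probes"] = 3
    elif mode == 1:
        call["mean_log2"] = -0.2 if call["type"] == "deletion" else 0.1
    else:
        call["end"] = call["start"] + 16_000_000
    return call


def simulate_cohorts(
    config: SimulationConfig,
    genes: pd.DataFrame,
    risk: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-subject CNV call table for the case and background cohorts.

    Each subject draws deletion events per gene from the baseline rate
    (multiplied by ``risk_multiplier`` at risk genes for case subjects only);
    an event may extend over adjacent genes.  Probe counts and mean log2
    ratios are drawn so that calls normally pass the true-positive filters,
    except for a configured fraction corrupted to violate one rule each.
    """
    _, _, rng = _streams(config.seed)
    gene_names = genes["gene"].to_numpy()
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    n_genes = len(gene_names)
    risk_mask = np.isin(gene_names, list(risk))

    rows: list[dict] = []
    for cohort, n_subjects in (("case", config.n_case), ("background", config.n_background)):
        rates = np.full(n_genes, config.baseline_deletion_rate)
        if cohort == "case":
            rates = np.where(risk_mask, rates * config.risk_multiplier, rates)
        if rates.max() == 0:
            continue
        hits = rng.random((n_subjects, n_genes)) < rates
        dup_hits = rng.random((n_subjects, n_genes)) < config.duplication_rate
        for subj_i in range(n_subjects):
            subject = f"{cohort}{subj_i:05d}"
            for cnv_type, hit_row in (("deletion", hits[subj_i]), ("duplication", dup_hits[subj_i])):
                for anchor in np.flatnonzero(hit_row):
                    span = 1
                    while (
                        span < config.max_span_genes
                        and anchor + span < n_genes
                        and rng.random() < config.span_continue_prob
                    ):
                        span += 1
                    last = anchor + span - 1
                    call = {
                        "subject": subject,
                        "cohort": cohort,
                        "chrom": "chr1",
                        "start": int(gstart[anchor] - rng.integers(0, 5000)),
                        "end": int(gend[last] + rng.integers(0, 5000)),
                        "type": cnv_type,
                        "n_probes": int(rng.integers(8, 60)),
                        "mean_log2": float(
                            rng.normal(-0.7, 0.12)
                            if cnv_type == "deletion"
                            else rng.normal(0.45, 0.08)
                        ),
                    }
                    call["start"] = max(1, call["start"])
                    if rng.random() < config.filter_fail_fraction:
                        call = _corrupt_call(call, rng)
                    rows.append(call)
    columns = ["subject", "cohort", "chrom", "start", "end", "type", "n_probes", "mean_log2"]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class SimulatedStudy:
    """All inputs of one synthetic study, bundled."""

    config: SimulationConfig
    bundle: KnowledgeBundle
    training: list[str]
    risk_genes: list[str]
    gene_models: pd.DataFrame
    calls: pd.DataFrame


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate knowledge sources, genome layout and cohorts in one call."""
    config = config or SimulationConfig()
    bundle, training = simulate_knowledge(config)
    risk = risk_genes(config, training)
    models = gene_models(config)
    calls = simulate_cohorts(config, models, risk)
    return SimulatedStudy(
        config=config,
        bundle=bundle,
        training=training,
        risk_genes=risk,
        gene_models=models,
        calls=calls,
    )
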