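"""Per-subject CNV call handling and cohort-level statistics.

Calls are probe-bounded intervals (1-based, closed coordinates in memory).
Erroneous calls are removed by size / probe-count / mean log2-ratio filters,
surviving calls are mapped to the genes they overlap by at least one base,
and distinct-subject deletion counts per gene feed the Bayes model.  Subject
level load statistics (maximum pathogenicity score, top-3 Bayes factors with
leave-one-subject-out correction) support case/control comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .bayes import (
    BayesConfig,
    GeneFrequencyRecord,
    background_rate_table,
    bayes_factor,
    compute_bayes_factors,
)

__all__ = [
    "CnvCall",
    "GeneModel",
    "SubjectLoad",
    "FilterConfig",
    "filter_calls",
    "genes_in_interval",
    "map_calls_to_genes",
    "gene_deletion_counts",
    "subject_max_pathogenicity",
    "loo_subject_bayes_factors",
    "subject_bayes_loads",
    "compare_cohorts",
]

CALL_COLUMNS = ("subject", "cohort", "chrom", "start", "end", "type", "n_probes", "mean_log2")


@dataclass(frozen=True)
class CnvCall:
    """One called copy-number interval for one subject (1-based, closed)."""

    subject: str
    cohort: str
    chrom: str
    start: int
    end: int
    type: str  # "deletion" | "duplication"
    n_probes: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.type not in ("deletion", "duplication"):
            raise ValueError(f"unknown call type {self.type!r}")


@dataclass(frozen=True)
class GeneModel:
    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")


@dataclass(frozen=True)
class SubjectLoad:
    """Top Bayes factors among a subject's deleted genes."""

    subject: str
    cohort: str
    top_genes: tuple[tuple[str, float], ...]  # (gene, BF) sorted descending, BF > 1
    max_pathogenicity: float

    def __post_init__(self) -> None:
        bfs = [bf for _, bf in self.top_genes]
        if any(bf <= 1 for bf in bfs):
            raise ValueError("top genes must have Bayes factor > 1")
        if bfs != sorted(bfs, reverse=True):
            raise ValueError("top genes must be sorted by descending Bayes factor")

    @property
    def max_bayes_factor(self) -> float:
        """Maximum BF; 1 by definition when no gene exceeds 1."""
        return self.top_genes[0][1] if self.top_genes else 1.0


@dataclass(frozen=True)
class FilterConfig:
    """True-positive call filters (sizes in base pairs)."""

    max_span_bp: int = 15_000_000
    min_probes: int = 4
    del_log2_max: float = -0.3
    dup_log2_min: float = 0.21


def filter_calls(calls: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep calls smaller than the span limit, with enough variant probes and
    a type-consistent mean log2 ratio (deletions below the deletion cutoff,
    duplications above the duplication cutoff).  Idempotent."""
    config = config or FilterConfig()
    span_ok = (calls["end"] - calls["start"]) < config.max_span_bp
    probes_ok = calls["n_probes"] >= config.min_probes
    log2 = calls["mean_log2"]
    type_ok = np.where(
        calls["type"] == "deletion",
        log2 < config.del_log2_max,
        log2 > config.dup_log2_min,
    )
    return calls.loc[span_ok & probes_ok & type_ok].copy()


def genes_in_interval(call: CnvCall, genes: Sequence[GeneModel]) -> set[str]:
    """Genes whose annotated span intersects the call interval by >= 1 base."""
    return {
        g.gene
        for g in genes
        if g.chrom == call.chrom and g.start <= call.end and g.end >= call.start
    }


def _gene_arrays(genes: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    by_chrom = {}
    for chrom, sub in genes.groupby("chrom"):
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["gene"].to_numpy(),
        )
    return by_chrom


def map_calls_to_genes(calls: pd.DataFrame, genes: pd.DataFrame) -> list[set[str]]:
    """Per-call overlapping gene sets (vectorised per chromosome).

    ``genes`` is a DataFrame with columns gene, chrom, start, end in the
    in-memory (1-based closed) convention.
    """
    by_chrom = _gene_arrays(genes)
    out: list[set[str]] = []
    for chrom, start, end in zip(calls["chrom"], calls["start"], calls["end"]):
        arrs = by_chrom.get(chrom)
        if arrs is None:
            out.append(set())
            continue
        gs, ge, names = arrs
        hit = (gs <= end) & (ge >= start)
        out.append(set(names[hit]))
    return out


def gene_deletion_counts(
    calls: pd.DataFrame, genes: pd.DataFrame, cohort: str
) -> pd.Series:
    """Distinct subjects of ``cohort`` with >= 1 deletion overlapping each gene.

    ``calls`` should already be filtered.  Duplications never contribute; a
    subject with several overlapping deletions of a gene counts once.
    """
    sub = calls[(calls["cohort"] == cohort) & (calls["type"] == "deletion")]
    hit_sets = map_calls_to_genes(sub, genes)
    per_gene: dict[str, set[str]] = {g: set() for g in genes["gene"]}
    for subject, hits in zip(sub["subject"], hit_sets):
        for g in hits:
            per_gene[g].add(subject)
    return pd.Series(
        {g: len(s) for g, s in per_gene.items()}, name=f"{cohort}_subjects"
    ).reindex(genes["gene"].to_numpy())


def subject_genes(
    calls: pd.DataFrame, genes: pd.DataFrame, cnv_type: str | None = "deletion"
) -> dict[str, set[str]]:
    """Genes hit per subject, optionally restricted to one call type."""
    sub = calls if cnv_type in (None, "both") else calls[calls["type"] == cnv_type]
    hit_sets = map_calls_to_genes(sub, genes)
    out: dict[str, set[str]] = {}
    for subject, hits in zip(sub["subject"], hit_sets):
        out.setdefault(subject, set()).update(hits)
    return out


def subject_max_pathogenicity(
    subject_calls: pd.DataFrame,
    genes: pd.DataFrame,
    scores: pd.Series,
    cnv_type: str = "deletion",
    exclude: Iterable[str] | None = None,
) -> float:
    """Maximum composite score among genes hit by one subject's calls.

    ``exclude`` removes genes (e.g. the training set) from consideration.
    NaN when the subject has no surviving call of the requested type or no
    scored gene is hit.
    """
    hit: set[str] = set()
    sub = (
        subject_calls
        if cnv_type == "both"
        else subject_calls[subject_calls["type"] == cnv_type]
    )
    for s in map_calls_to_genes(sub, genes):
        hit |= s
    if exclude is not None:
        hit -= set(exclude)
    vals = scores.reindex(sorted(hit)).dropna()
    if vals.empty:
        return float("nan")
    return float(vals.max())


def loo_subject_bayes_factors(
    subject: str,
    cohort: str,
    deleted_genes: Iterable[str],
    contributed_genes: Iterable[str],
    freq: pd.DataFrame,
    scores: pd.Series,
    config: BayesConfig | None = None,
    max_pathogenicity: float = float("nan"),
    top_n: int = 3,
) -> SubjectLoad:
    """Leave-one-subject-out Bayes factors for one subject's deleted genes.

    ``contributed_genes`` are the genes whose case count includes this
    subject (empty for subjects outside the case frequency cohort); their
    k_case is decremented by one before recomputation so a subject's own
    deletion cannot inflate their score.
    """
    config = config or BayesConfig()
    deleted = sorted(set(deleted_genes) & set(freq.index))
    contributed = set(contributed_genes)
    if not contributed <= set(freq.index):
        raise ValueError("contributed genes must appear in the frequency table")
    n_bg = int(freq["n_bg"].iloc[0])
    rates = background_rate_table(freq["k_bg"], n_bg, config.pseudo_fraction)
    results: list[tuple[str, float]] = []
    for gene in deleted:
        row = freq.loc[gene]
        k_case = int(row["k_case"])
        if gene in contributed:
            k_case -= 1
            if k_case < 0:
                raise ValueError(
                    f"{gene}: leave-one-out decrement below zero (bookkeeping violation)"
                )
        rec = GeneFrequencyRecord(
            gene=gene,
            k_case=k_case,
            n_case=int(row["n_case"]),
            k_bg=int(row["k_bg"]),
            n_bg=int(row["n_bg"]),
        )
        s = float(scores.get(gene, 0.0))
        if np.isnan(s):
            s = 0.0
        res = bayes_factor(rec, s, float(rates.loc[gene]), config)
        if res.bayes_factor > 1.0:
            results.append((gene, res.bayes_factor))
    results.sort(key=lambda t: (-t[1], t[0]))
    return SubjectLoad(
        subject=subject,
        cohort=cohort,
        top_genes=tuple(results[:top_n]),
        max_pathogenicity=max_pathogenicity,
    )


def subject_bayes_loads(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    scores: pd.Series,
    freq: pd.DataFrame,
    case_cohort: str = "case",
    config: BayesConfig | None = None,
    filter_config: FilterConfig | None = None,
) -> list[SubjectLoad]:
    """Per-subject load statistics for every subject with surviving calls.

    Subjects labelled with ``case_cohort`` are assumed to be members of the
    case frequency cohort, so their contribution (one per gene they delete)
    is removed before their Bayes factors are computed; other subjects use
    the global table unchanged.
    """
    config = config or BayesConfig()
    kept = filter_calls(calls, filter_config)
    per_subject = subject_genes(kept, genes, "deletion")
    cohort_of = kept.drop_duplicates("subject").set_index("subject")["cohort"]
    loads = []
    for subject in sorted(per_subject):
        deleted = per_subject[subject]
        cohort = str(cohort_of.loc[subject])
        contributed = deleted & set(freq.index) if cohort == case_cohort else set()
        max_path = subject_max_pathogenicity(
            kept[kept["subject"] == subject], genes, scores, "deletion"
        )
        loads.append(
            loo_subject_bayes_factors(
                subject, cohort, deleted, contributed, freq, scores, config,
                max_pathogenicity=max_path,
            )
        )
    return loads


def compare_cohorts(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Unpaired rank-based location test (Mann-Whitney / rank-sum).

    Returns (U statistic, p-value).  When every value in both groups is
    identical there is no location information and p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all values tied across both groups; p = 1")
        return float(a.size * b.size / 2.0), 1.0
    stat, p = mannwhitneyu(a, b, alternative=alternative)
    return float(stat), float(p)
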