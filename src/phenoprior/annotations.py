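"""Category-based annotation features.

Each knowledge source (GO-like terms, mouse-phenotype-like terms, pathway
membership, miRNA target sets) is modelled as a flat collection of gene-set
categories over a declared gene universe.  A gene's raw feature score for a
source is built in two steps: first the categories significantly enriched for
the phenotype's training genes are selected (one-sided hypergeometric test
with odds-ratio and minimum-overlap guards), then the gene receives the sum of
``-ln(p)`` weights over the enriched categories that contain it.  Genes absent
from a source's universe are scored as missing rather than zero: absence of
evidence is not evidence of absence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "AnnotationSystem",
    "EnrichedCategory",
    "EnrichmentThresholds",
    "select_enriched_categories",
    "raw_match_score",
    "match_scores",
]

_P_FLOOR = 1e-300  # keeps -ln(p) finite when the tail underflows


@dataclass(frozen=True)
class EnrichmentThresholds:
    """Cutoffs defining an enriched category.

    Parameters
    ----------
    max_p
        Largest admissible one-sided hypergeometric p-value.
    min_odds_ratio
        Smallest admissible odds ratio of the 2x2 training/category table
        (Haldane 0.5 correction when any cell is zero).
    min_training
        Minimum number of training genes annotated to the category.
    """

    max_p: float = 0.01
    min_odds_ratio: float = 2.0
    min_training: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.max_p <= 1.0):
            raise ValueError(f"max_p must be in (0, 1], got {self.max_p}")
        if self.min_training < 0:
            raise ValueError("min_training must be >= 0")
        if self.min_odds_ratio < 0:
            raise ValueError("min_odds_ratio must be >= 0")


@dataclass(frozen=True)
class EnrichedCategory:
    """A category passing the enrichment cutoffs, with its match weight."""

    category: str
    p_value: float
    odds_ratio: float
    n_training: int
    weight: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")
        if self.n_training < 0 or self.weight < 0:
            raise ValueError("n_training and weight must be nonnegative")


@dataclass
class AnnotationSystem:
    """A named, flat collection of gene-set categories.

    ``universe`` is the set of genes the source makes any statement about;
    genes outside it cannot be scored by this source.
    """

    name: str
    categories: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.categories = {k: frozenset(v) for k, v in self.categories.items()}
        self.universe = frozenset(self.universe)
        for cat, members in self.categories.items():
            if not members:
                raise ValueError(f"category {cat!r} is empty")
            if not members <= self.universe:
                stray = sorted(members - self.universe)[:3]
                raise ValueError(
                    f"category {cat!r} contains genes outside the universe: {stray}"
                )

    @classmethod
    def from_categories(
        cls,
        name: str,
        categories: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
    ) -> "AnnotationSystem":
        cats = {k: frozenset(v) for k, v in categories.items()}
        if universe is None:
            uni: frozenset[str] = frozenset().union(*cats.values()) if cats else frozenset()
        else:
            uni = frozenset(universe)
        return cls(name=name, categories=cats, universe=uni)

    def __contains__(self, gene: str) -> bool:
        return gene in self.universe


def _odds_ratio(k: int, n_cat: int, n_train: int, n_universe: int) -> float:
    """Odds ratio of the 2x2 (in category x in training) table.

    Haldane correction: add 0.5 to every cell when any cell is zero.
    """
    a = k
    b = n_cat - k
    c = n_train - k
    d = n_universe - n_cat - n_train + k
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def select_enriched_categories(
    system: AnnotationSystem,
    training: Iterable[str],
    thresholds: EnrichmentThresholds | None = None,
) -> list[EnrichedCategory]:
    """Select categories enriched for the training genes.

    The test is the one-sided hypergeometric upper tail
    P(X >= k | N, K, n) with N = |universe|, K = |training in universe|,
    n = |category|, k = |category intersect training|.  A category equal to
    the whole universe has an undefined odds ratio and is excluded with a
    warning.

    Raises
    ------
    ValueError
        If no training gene is covered by the system's universe, or the
        universe has fewer than 2 genes.
    """
    thresholds = thresholds or EnrichmentThresholds()
    train_u = frozenset(training) & system.universe
    if not train_u:
        raise ValueError(
            f"system {system.name!r}: no training gene in its universe; unusable"
        )
    n_universe = len(system.universe)
    if n_universe < 2:
        raise ValueError(f"system {system.name!r}: universe has < 2 genes")
    n_train = len(train_u)

    selected: list[EnrichedCategory] = []
    for cat, members in system.categories.items():
        if members == system.universe:
            warnings.warn(
                f"system {system.name!r}: category {cat!r} equals the whole "
                "universe; odds ratio undefined, excluded",
                stacklevel=2,
            )
            continue
        k = len(members & train_u)
        if k < thresholds.min_training:
            continue
        p = float(hypergeom.sf(k - 1, n_universe, n_train, len(members)))
        p = min(max(p, _P_FLOOR), 1.0)
        if p > thresholds.max_p:
            continue
        orat = _odds_ratio(k, len(members), n_train, n_universe)
        if orat < thresholds.min_odds_ratio:
            continue
        selected.append(
            EnrichedCategory(
                category=cat,
                p_value=p,
                odds_ratio=orat,
                n_training=k,
                weight=-math.log(p),
            )
        )
    return selected


def raw_match_score(
    gene: str,
    enriched: Iterable[EnrichedCategory],
    system: AnnotationSystem,
) -> float:
    """Additive match score of one gene: sum of weights of the enriched
    categories containing it.

    Returns ``nan`` (missing) for genes outside the system's universe; genes
    in the universe but in no enriched category score 0.
    """
    if gene not in system.universe:
        return float("nan")
    return float(
        sum(ec.weight for ec in enriched if gene in system.categories[ec.category])
    )


def match_scores(
    genes: Iterable[str],
    enriched: Iterable[EnrichedCategory],
    system: AnnotationSystem,
) -> dict[str, float]:
    """Vector version of :func:`raw_match_score` over many genes."""
    nan = float("nan")
    out: dict[str, float] = {
        g: (0.0 if g in system.universe else nan) for g in genes
    }
    # accumulate category weights over members: O(n_genes + sum of category sizes)
    for ec in enriched:
        w = ec.weight
        for g in system.categories[ec.category]:
            if g in out and out[g] == out[g]:  # present and not NaN
                out[g] += w
    return out
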