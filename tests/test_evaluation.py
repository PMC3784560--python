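"""Leave-one-out cross-validation, ROC/AUC, and the decision-rule sweep."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phenoprior import (
    AnnotationSystem,
    KnowledgeBundle,
    ScoreConfig,
    decision_rule_sweep,
    loo_crossval,
    roc,
    score_genes,
)
from phenoprior.cohort import SubjectLoad


def pairwise_auc_oracle(scores: dict, positives: set) -> float:
    """AUC as the probability a positive outranks a negative (ties = 1/2)."""
    pos = [s for g, s in scores.items() if g in positives]
    neg = [s for g, s in scores.items() if g not in positives]
    wins = 0.0
    for p, n in itertools.product(pos, neg):
        wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def tiny_bundle(n_genes=60, n_training=6, seed=0):
    """A hand-sized bundle with signal: training genes share one exclusive
    category, one elevated tissue pair, and a network clique."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    training = genes[:n_training]
    cats = {
        "shared": set(training),  # exclusive training category
        "noise1": set(genes[20:35]),
        "noise2": set(genes[40:52]),
    }
    system = AnnotationSystem.from_categories("go", cats, genes)
    tissues = [f"T{i}" for i in range(12)]
    vals = rng.normal(5, 1, (n_genes, 12))
    vals[:n_training, :2] += 3.0
    expr = pd.DataFrame(vals, index=genes, columns=tissues)
    network = nx.Graph()
    network.add_nodes_from(genes)
    for u, v in itertools.combinations(training, 2):
        network.add_edge(u, v)
    for _ in range(80):
        u, v = rng.choice(genes, 2, replace=False)
        if u != v:
            network.add_edge(u, v)
    bundle = KnowledgeBundle(
        systems={"go": system}, expression=expr, network=network, genes=tuple(genes)
    )
    return bundle, training


class TestLooCrossval:
    def test_exclusive_category_survives_hold_out(self):
        """Training genes sharing one exclusive category: the held-out gene
        still scores positive on that system because the category remains
        enriched through the other members."""
        bundle, training = tiny_bundle()
        cv_scores, status = loo_crossval(bundle, training)
        assert all(s == "ok" for s in status.values())
        for t in training:
            assert cv_scores.loc[t] > 0

    def test_crossval_scores_differ_from_full_training_scores(self):
        bundle, training = tiny_bundle()
        full = score_genes(bundle, training)["composite"]
        cv_scores, _ = loo_crossval(bundle, training)
        # background genes are scored once, with the full set
        background = [g for g in bundle.genes if g not in training]
        pd.testing.assert_series_equal(
            cv_scores.loc[background], full.loc[background], check_names=False
        )
        # held-out training genes lose their self-contribution
        assert any(
            cv_scores.loc[t] != pytest.approx(full.loc[t]) for t in training
        )

    def test_unannotated_isolated_training_gene_scores_zero(self):
        """A training gene absent from every knowledge source has every
        feature missing, so its cross-validated composite is exactly 0."""
        bundle, training = tiny_bundle()
        orphan = "orphan"
        genes = bundle.genes + (orphan,)
        # absent from the annotation universe, expression matrix and network
        bundle2 = KnowledgeBundle(
            systems=bundle.systems,
            expression=bundle.expression,
            network=bundle.network,
            genes=genes,
        )
        cv_scores, status = loo_crossval(bundle2, training + [orphan])
        assert status[orphan] == "ok"
        assert cv_scores.loc[orphan] == 0.0

    def test_requires_three_training_genes(self):
        bundle, _ = tiny_bundle()
        with pytest.raises(ValueError, match=">= 3"):
            loo_crossval(bundle, ["g00", "g01"])


class TestRoc:
    def test_perfect_separation(self):
        scores = {"a": 4.0, "b": 3.0, "c": 1.0, "d": 0.5}
        _, auc = roc(scores, {"a", "b"})
        assert auc == 1.0

    def test_enumerated_pairwise_example(self):
        """4 genes scored (4,3,2,1), positives ranks 1 and 3 -> AUC 0.75."""
        scores = {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}
        positives = {"a", "c"}
        _, auc = roc(scores, positives)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(pairwise_auc_oracle(scores, positives))

    def test_matches_pairwise_oracle_with_ties(self, rng):
        genes = [f"g{i}" for i in range(40)]
        scores = {g: float(rng.integers(0, 6)) for g in genes}  # many ties
        positives = set(rng.choice(genes, size=10, replace=False))
        _, auc = roc(scores, positives)
        assert auc == pytest.approx(pairwise_auc_oracle(scores, positives), rel=1e-12)

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        genes = [f"g{i}" for i in range(60)]
        scores = {g: float(rng.normal()) for g in genes}
        positives = set(rng.choice(genes, size=15, replace=False))
        labels = [1 if g in positives else 0 for g in genes]
        _, auc = roc(scores, positives)
        assert auc == pytest.approx(
            roc_auc_score(labels, [scores[g] for g in genes]), rel=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        genes = [f"g{i}" for i in range(30)]
        scores = {g: float(rng.normal()) for g in genes}
        positives = set(genes[:8])
        _, auc1 = roc(scores, positives)
        _, auc2 = roc({g: math.exp(s) for g, s in scores.items()}, positives)
        assert auc1 == pytest.approx(auc2, rel=1e-12)

    def test_random_scores_near_half(self, rng):
        genes = [f"g{i}" for i in range(4000)]
        scores = {g: float(rng.normal()) for g in genes}
        positives = set(rng.choice(genes, size=1000, replace=False))
        _, auc = roc(scores, positives)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_sensitivity_nonincreasing_in_threshold(self, rng):
        genes = [f"g{i}" for i in range(50)]
        scores = {g: float(rng.normal()) for g in genes}
        points, _ = roc(scores, set(genes[:12]))
        ordered = sorted(points, key=lambda p: p.threshold)
        sens = [p.sensitivity for p in ordered]
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_positives_must_be_strict_subset(self):
        with pytest.raises(ValueError):
            roc({"a": 1.0, "b": 2.0}, {"a", "b"})
        with pytest.raises(ValueError):
            roc({"a": 1.0, "b": 2.0}, {"zzz"})


def load(subject, cohort, *bfs, max_path=float("nan")):
    return SubjectLoad(
        subject=subject,
        cohort=cohort,
        top_genes=tuple((f"g{i}", bf) for i, bf in enumerate(bfs)),
        max_pathogenicity=max_path,
    )


class TestDecisionRuleSweep:
    loads = [
        load("c1", "case", 5.0),
        load("c2", "case"),  # no BF > 1 gene: max BF = 1 by definition
        load("b1", "background", 2.0),
        load("b2", "background"),
    ]

    def test_counting_example(self):
        """Cases with max BF (5, 1), backgrounds (2, 1), cutoff 2:
        sensitivity 0.5, specificity 1.0."""
        points = {p.threshold: p for p in decision_rule_sweep(self.loads, [2.0])}
        assert points[2.0].sensitivity == 0.5
        assert points[2.0].specificity == 1.0

    def test_extreme_cutoffs(self):
        points = decision_rule_sweep(self.loads, [0.5, 100.0])
        below, above = points
        assert below.sensitivity == 1.0 and below.specificity == 0.0
        assert above.sensitivity == 0.0 and above.specificity == 1.0

    def test_monotone_in_cutoff(self, rng):
        loads = [
            load(f"s{i}", "case" if i % 2 else "background",
                 *( [float(rng.uniform(1.01, 30))] if rng.random() < 0.8 else [] ))
            for i in range(50)
        ]
        cutoffs = sorted(rng.uniform(0.5, 35, size=20).tolist())
        points = decision_rule_sweep(loads, cutoffs)
        sens = [p.sensitivity for p in points]
        spec = [p.specificity for p in points]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_requires_both_cohorts(self):
        with pytest.raises(ValueError):
            decision_rule_sweep([load("c1", "case", 2.0)], [1.0])
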