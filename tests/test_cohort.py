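"""Call filtering, interval-to-gene mapping, distinct-subject counting,
leave-one-subject-out Bayes factors and the cohort comparison test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phenoprior import (
    BayesConfig,
    CnvCall,
    compare_cohorts,
    compute_bayes_factors,
    filter_calls,
    gene_deletion_counts,
    genes_in_interval,
    loo_subject_bayes_factors,
    subject_max_pathogenicity,
)
from phenoprior.cohort import GeneModel, subject_genes


def call_row(subject="s1", cohort="case", chrom="chr1", start=100, end=200,
             type="deletion", n_probes=10, mean_log2=-0.6):
    return dict(subject=subject, cohort=cohort, chrom=chrom, start=start, end=end,
                type=type, n_probes=n_probes, mean_log2=mean_log2)


def frame(*rows):
    return pd.DataFrame(list(rows))


class TestFilterCalls:
    def test_interval_size_limit(self):
        big = call_row(start=1, end=16_000_001)
        ok = call_row(start=1, end=1_000_000)
        kept = filter_calls(frame(big, ok))
        assert len(kept) == 1 and kept.iloc[0]["end"] == 1_000_000

    def test_probe_count_minimum(self):
        kept = filter_calls(frame(call_row(n_probes=3, mean_log2=-0.5)))
        assert kept.empty
        kept = filter_calls(frame(call_row(n_probes=4, mean_log2=-0.5)))
        assert len(kept) == 1

    def test_log2_thresholds_are_type_consistent(self):
        shallow_del = call_row(mean_log2=-0.25)
        good_dup = call_row(type="duplication", mean_log2=0.25, n_probes=5,
                            start=1, end=1_000_000)
        inverted_del = call_row(mean_log2=0.5)  # deletion with gain-like log2
        kept = filter_calls(frame(shallow_del, good_dup, inverted_del))
        assert len(kept) == 1 and kept.iloc[0]["type"] == "duplication"

    def test_idempotent(self):
        calls = frame(
            call_row(), call_row(n_probes=2), call_row(type="duplication", mean_log2=0.3)
        )
        once = filter_calls(calls)
        twice = filter_calls(once)
        pd.testing.assert_frame_equal(once, twice)


class TestGenesInInterval:
    genes = [
        GeneModel("g1", "chr1", 50, 99),
        GeneModel("g2", "chr1", 50, 100),
        GeneModel("g3", "chr1", 150, 160),
        GeneModel("g4", "chr1", 200, 300),
        GeneModel("g5", "chr2", 100, 200),
    ]

    def test_closed_interval_overlap_enumeration(self):
        call = CnvCall("s", "case", "chr1", 100, 200, "deletion", 10, -0.5)
        assert genes_in_interval(call, self.genes) == {"g2", "g3", "g4"}

    def test_single_base_overlap_counts(self):
        call = CnvCall("s", "case", "chr1", 100, 100, "deletion", 10, -0.5)
        assert genes_in_interval(call, self.genes) == {"g2"}

    def test_other_chromosome_excluded(self):
        call = CnvCall("s", "case", "chr2", 100, 200, "deletion", 10, -0.5)
        assert genes_in_interval(call, self.genes) == {"g5"}


class TestGeneDeletionCounts:
    def test_distinct_subject_rule(self, toy_gene_models):
        calls = frame(
            call_row(subject="s1", start=140, end=170),
            call_row(subject="s1", start=150, end=165),  # same subject, same gene
            call_row(subject="s2", start=145, end=155),
        )
        counts = gene_deletion_counts(calls, toy_gene_models, "case")
        assert counts["gB"] == 2

    def test_duplications_never_contribute(self, toy_gene_models):
        calls = frame(
            call_row(subject="s1", start=140, end=170, type="duplication", mean_log2=0.4)
        )
        counts = gene_deletion_counts(calls, toy_gene_models, "case")
        assert counts.sum() == 0

    def test_counts_partition_over_cohorts(self, toy_gene_models):
        rows = [
            call_row(subject=f"s{i}", cohort=c, start=140, end=170)
            for i, c in enumerate(["case", "case", "background", "case"])
        ]
        calls = frame(*rows)
        case = gene_deletion_counts(calls, toy_gene_models, "case")
        bg = gene_deletion_counts(calls, toy_gene_models, "background")
        pooled = calls.assign(cohort="all")
        total = gene_deletion_counts(pooled, toy_gene_models, "all")
        pd.testing.assert_series_equal(case + bg, total, check_names=False)


class TestSubjectMaxPathogenicity:
    scores = pd.Series({"gA": 0.2, "gB": 1.7, "gC": -0.4, "gD": 3.0})

    def test_maximum_over_deleted_genes(self, toy_gene_models):
        calls = frame(call_row(start=60, end=250))  # hits gA, gB, gC
        assert subject_max_pathogenicity(calls, toy_gene_models, self.scores) == 1.7

    def test_exclusion_flag_removes_training_gene(self, toy_gene_models):
        calls = frame(call_row(start=60, end=250))
        got = subject_max_pathogenicity(
            calls, toy_gene_models, self.scores, exclude={"gB"}
        )
        assert got == pytest.approx(0.2)

    def test_deletion_only_request_ignores_duplications(self, toy_gene_models):
        calls = frame(
            call_row(start=60, end=110),  # deletion: gA only
            call_row(start=140, end=170, type="duplication", mean_log2=0.4),  # dup: gB
        )
        assert subject_max_pathogenicity(calls, toy_gene_models, self.scores) == 0.2

    def test_no_surviving_calls_is_missing(self, toy_gene_models):
        calls = frame(call_row(type="duplication", mean_log2=0.4))
        got = subject_max_pathogenicity(calls, toy_gene_models, self.scores, "deletion")
        assert math.isnan(got)


class TestLooSubjectBayesFactors:
    freq = pd.DataFrame(
        {
            "k_case": [5, 1, 0],
            "n_case": [1000] * 3,
            "k_bg": [1, 1, 1],
            "n_bg": [2000] * 3,
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene"),
    )
    scores = pd.Series({"gA": 2.0, "gB": 1.5, "gC": 1.0})

    def test_subject_outside_frequency_cohort_matches_global_table(self):
        global_table = compute_bayes_factors(self.freq, self.scores)
        load = loo_subject_bayes_factors(
            "s1", "background", ["gA", "gB"], contributed_genes=[],
            freq=self.freq, scores=self.scores,
        )
        got = dict(load.top_genes)
        for gene in got:
            assert got[gene] == pytest.approx(global_table.loc[gene, "bayes_factor"])

    def test_sole_contributor_decrement(self):
        """A gene whose single case observation came from this subject is
        recomputed at k_case = 0, where the floor engages."""
        load = loo_subject_bayes_factors(
            "s1", "case", ["gB"], contributed_genes=["gB"],
            freq=self.freq, scores=self.scores,
        )
        assert load.top_genes == ()  # k_case=0 with positive score -> BF 1
        assert load.max_bayes_factor == 1.0

    def test_decrement_below_zero_errors(self):
        freq = self.freq.copy()
        freq.loc["gC", "k_case"] = 0
        with pytest.raises(ValueError, match="bookkeeping"):
            loo_subject_bayes_factors(
                "s1", "case", ["gC"], contributed_genes=["gC"],
                freq=freq, scores=self.scores,
            )

    def test_remove_and_re_add_restores_global_table(self):
        """Leave-one-out round trip: decrementing a subject's contribution and
        adding it back reproduces the global Bayes factors exactly."""
        global_table = compute_bayes_factors(self.freq, self.scores)
        removed = self.freq.copy()
        removed.loc[["gA", "gB"], "k_case"] -= 1
        restored = removed.copy()
        restored.loc[["gA", "gB"], "k_case"] += 1
        table2 = compute_bayes_factors(restored, self.scores)
        pd.testing.assert_frame_equal(global_table, table2)

    def test_top_genes_sorted_and_capped_at_three(self):
        freq = pd.DataFrame(
            {
                "k_case": [8, 6, 5, 4],
                "n_case": [1000] * 4,
                "k_bg": [1] * 4,
                "n_bg": [2000] * 4,
            },
            index=pd.Index(list("abcd"), name="gene"),
        )
        scores = pd.Series(2.0, index=list("abcd"))
        load = loo_subject_bayes_factors(
            "s1", "background", list("abcd"), [], freq, scores
        )
        assert len(load.top_genes) == 3
        bfs = [bf for _, bf in load.top_genes]
        assert bfs == sorted(bfs, reverse=True)


class TestCompareCohorts:
    def test_identical_lists_give_p_one(self):
        _, p = compare_cohorts([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_one_sided_p_by_enumeration(self):
        """Fully separated groups of 3: one-sided p = 1/C(6,3) = 0.05."""
        _, p = compare_cohorts([10, 11, 12], [1, 2, 3], alternative="greater")
        assert p == pytest.approx(1 / math.comb(6, 3), rel=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.normal(size=20).tolist()
        b = rng.normal(loc=1.0, size=25).tolist()
        stat1, p1 = compare_cohorts(a, b)
        stat2, p2 = compare_cohorts(np.exp(a).tolist(), np.exp(b).tolist())
        assert stat1 == pytest.approx(stat2)
        assert p1 == pytest.approx(p2)

    def test_all_tied_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = compare_cohorts([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_too_small_groups_error(self):
        with pytest.raises(ValueError):
            compare_cohorts([1.0], [1.0, 2.0])
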