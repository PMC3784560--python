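"""High-level orchestration: from inputs to scores, Bayes factors and loads.

Convenience layer used by the command-line interface, the examples and the
test suite; every step delegates to the underlying modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bayes import BayesConfig, compute_bayes_factors
from .cohort import (
    FilterConfig,
    SubjectLoad,
    compare_cohorts,
    filter_calls,
    gene_deletion_counts,
    subject_bayes_loads,
)
from .evaluation import RocPoint, decision_rule_sweep, loo_crossval, roc
from .pipeline import KnowledgeBundle, ScoreConfig, score_genes

__all__ = ["StudyResults", "build_frequency_table", "run_study"]


def build_frequency_table(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    n_case: int,
    n_bg: int,
    case_cohort: str = "case",
    bg_cohort: str = "background",
    filter_config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Per-gene distinct-subject deletion counts for the two frequency cohorts.

    ``n_case`` / ``n_bg`` are the full cohort sizes (subjects without calls
    still count in the denominator).
    """
    kept = filter_calls(calls, filter_config)
    k_case = gene_deletion_counts(kept, genes, case_cohort)
    k_bg = gene_deletion_counts(kept, genes, bg_cohort)
    return pd.DataFrame(
        {
            "k_case": k_case.to_numpy(),
            "n_case": n_case,
            "k_bg": k_bg.to_numpy(),
            "n_bg": n_bg,
        },
        index=pd.Index(genes["gene"], name="gene"),
    )


@dataclass
class StudyResults:
    scores: pd.DataFrame
    frequency: pd.DataFrame
    bayes: pd.DataFrame
    loads: list[SubjectLoad]
    sweep: list[RocPoint]
    crossval_scores: pd.Series | None = None
    crossval_auc: float | None = None
    load_comparison: tuple[float, float] | None = None


def run_study(
    bundle: KnowledgeBundle,
    training: list[str],
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    n_case: int,
    n_bg: int,
    score_config: ScoreConfig | None = None,
    bayes_config: BayesConfig | None = None,
    filter_config: FilterConfig | None = None,
    crossval: bool = False,
) -> StudyResults:
    """Run the full analysis on one set of inputs.

    Composite scores, the per-gene Bayes-factor table, leave-one-subject-out
    per-subject loads, the case/background rank-sum comparison of maximum
    Bayes factors, and the decision-rule sensitivity/specificity sweep.
    Optionally adds leave-one-out cross-validated scores and their AUC.
    """
    score_config = score_config or ScoreConfig()
    bayes_config = bayes_config or BayesConfig()
    table = score_genes(bundle, training, score_config)
    freq = build_frequency_table(
        calls, genes, n_case, n_bg, filter_config=filter_config
    )
    bayes = compute_bayes_factors(freq, table["composite"], bayes_config)
    loads = subject_bayes_loads(
        calls, genes, table["composite"], freq,
        config=bayes_config, filter_config=filter_config,
    )
    sweep = decision_rule_sweep(loads)
    case_bfs = [l.max_bayes_factor for l in loads if l.cohort == "case"]
    bg_bfs = [l.max_bayes_factor for l in loads if l.cohort != "case"]
    comparison = (
        compare_cohorts(case_bfs, bg_bfs, alternative="greater")
        if len(case_bfs) >= 2 and len(bg_bfs) >= 2
        else None
    )
    results = StudyResults(
        scores=table,
        frequency=freq,
        bayes=bayes,
        loads=loads,
        sweep=sweep,
        load_comparison=comparison,
    )
    if crossval:
        cv_scores, _ = loo_crossval(bundle, training, score_config)
        _, auc = roc(cv_scores, set(training))
        results.crossval_scores = cv_scores
        results.crossval_auc = auc
    return results
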