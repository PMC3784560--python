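"""Cross-validation, ROC summaries, and the decision-rule sweep.

Leave-one-out cross-validation re-runs the whole scoring pipeline per held
out training gene -- enrichment selection, tissue contrast, communicability
target set, tail fractions and standardisation are all recomputed from the
remaining training genes -- so the held-out gene's score never uses its own
training membership anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectLoad
from .pipeline import KnowledgeBundle, ScoreConfig, score_genes

__all__ = ["RocPoint", "loo_crossval", "roc", "decision_rule_sweep"]


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise ValueError("sensitivity/specificity outside [0, 1]")


def loo_crossval(
    bundle: KnowledgeBundle,
    training: Iterable[str],
    config: ScoreConfig | None = None,
) -> tuple[pd.Series, dict[str, str]]:
    """Cross-validated composite scores.

    Each training gene is scored by a pipeline re-run with it removed from
    the training set; background genes keep their full-training scores.
    Returns the score series and a per-fold status map ("ok" or the error
    message) -- a failed fold is reported, never silently skipped.
    """
    training = sorted(set(training))
    if len(training) < 3:
        raise ValueError("leave-one-out needs >= 3 training genes")
    config = config or ScoreConfig()
    full = score_genes(bundle, training, config)
    scores = full["composite"].copy()
    status: dict[str, str] = {}
    for held_out in training:
        fold_training = [t for t in training if t != held_out]
        try:
            fold = score_genes(bundle, fold_training, config)
            scores.loc[held_out] = fold.loc[held_out, "composite"]
            status[held_out] = "ok"
        except Exception as exc:  # noqa: BLE001 - fold failure is reported, not raised
            scores.loc[held_out] = np.nan
            status[held_out] = f"failed: {exc}"
    return scores, status


def roc(
    scores: pd.Series | dict[str, float], positives: Iterable[str]
) -> tuple[list[RocPoint], float]:
    """ROC curve over score thresholds and its trapezoidal AUC.

    A gene is predicted positive when its score >= threshold; tied scores
    are grouped into a single threshold.  ``positives`` must be a non-empty
    strict subset of the scored genes.
    """
    s = pd.Series(scores, dtype=float).dropna()
    pos = set(positives) & set(s.index)
    if not pos:
        raise ValueError("no positive gene among the scored genes")
    if len(pos) == len(s):
        raise ValueError("positives must be a strict subset of scored genes")
    labels = np.asarray(s.index.isin(pos), dtype=float)
    values = s.to_numpy()
    order = np.argsort(-values, kind="mergesort")
    values, labels = values[order], labels[order]
    n_pos = labels.sum()
    n_neg = labels.size - n_pos

    points: list[RocPoint] = []
    tp = fp = 0.0
    # iterate threshold groups (distinct score values, descending)
    i = 0
    xs = [0.0]
    ys = [0.0]
    while i < labels.size:
        j = i
        while j < labels.size and values[j] == values[i]:
            j += 1
        tp += labels[i:j].sum()
        fp += (j - i) - labels[i:j].sum()
        sens = tp / n_pos
        spec = 1.0 - fp / n_neg
        points.append(RocPoint(threshold=float(values[i]), sensitivity=sens, specificity=spec))
        xs.append(fp / n_neg)
        ys.append(sens)
        i = j
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def decision_rule_sweep(
    loads: Sequence[SubjectLoad],
    cutoffs: Sequence[float] | None = None,
    case_cohort: str = "case",
) -> list[RocPoint]:
    """Sensitivity/specificity of "max Bayes factor > cutoff" per cutoff.

    A subject with no gene above BF 1 has a maximum Bayes factor of 1 by
    definition.  Sensitivity counts case subjects strictly above the cutoff;
    specificity counts non-case subjects at or below it.
    """
    case_bfs = np.array(
        [l.max_bayes_factor for l in loads if l.cohort == case_cohort], dtype=float
    )
    bg_bfs = np.array(
        [l.max_bayes_factor for l in loads if l.cohort != case_cohort], dtype=float
    )
    if case_bfs.size == 0 or bg_bfs.size == 0:
        raise ValueError("both case and comparison subjects are required")
    if cutoffs is None:
        cutoffs = sorted(set(np.concatenate([case_bfs, bg_bfs]).tolist()) | {1.0})
    return [
        RocPoint(
            threshold=float(t),
            sensitivity=float(np.mean(case_bfs > t)),
            specificity=float(np.mean(bg_bfs <= t)),
        )
        for t in cutoffs
    ]
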