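"""Standardisation of raw feature scores and composite fusion.

Every feature's raw scores are converted to a common metric: for each gene,
the fraction of training genes and of all background genes whose raw score
is at least as high, and the natural log of the ratio of those fractions
(the "tail log-ratio").  A gene resembling the training set sits in a thin
training tail relative to the background tail, giving a large positive value.
The log-ratios are z-standardised per feature, and the composite score of a
gene is the mean of its available standardised features (0 if none).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["tail_logratio", "tail_logratio_table", "standardize", "compose"]

#: default feature column order, mirroring the six knowledge sources
FEATURE_ORDER = ("go", "mgi", "kegg", "mirna", "expression", "ppi")


def _tail_fraction(score: float, values: np.ndarray, floor_n: int) -> float:
    frac = float(np.count_nonzero(values >= score)) / values.size
    if frac == 0.0:
        frac = 1.0 / (2 * floor_n)
    return frac


def tail_logratio(
    score: float,
    training_scores: Sequence[float],
    background_scores: Sequence[float],
) -> float:
    """ln of (training tail fraction / background tail fraction) at ``score``.

    Tail fractions use an inclusive ``>=`` comparison.  A zero tail fraction
    is floored at 1/(2n) for the corresponding set so the log stays finite.
    """
    tr = np.asarray(training_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if tr.size == 0 or bg.size == 0:
        raise ValueError("training and background score sets must be non-empty")
    return float(
        np.log(_tail_fraction(score, tr, tr.size) / _tail_fraction(score, bg, bg.size))
    )


def tail_logratio_table(
    scores: pd.Series, training: set[str] | Sequence[str]
) -> pd.Series:
    """Tail log-ratios for every gene in ``scores`` (NaN-aware, vectorised).

    The background set is every gene with a defined raw score (training genes
    included -- they are ordinary genes too); the training set is the defined
    scores of ``training``.  Genes with missing raw scores get NaN.
    """
    defined = scores.dropna()
    if defined.empty:
        raise ValueError("no defined raw scores")
    tr_vals = defined[defined.index.isin(set(training))].to_numpy()
    if tr_vals.size == 0:
        raise ValueError("no training gene has a defined raw score")
    bg_vals = defined.to_numpy()

    tr_sorted = np.sort(tr_vals)
    bg_sorted = np.sort(bg_vals)
    x = defined.to_numpy()
    # count of values >= x via searchsorted on the sorted arrays
    tr_ge = tr_sorted.size - np.searchsorted(tr_sorted, x, side="left")
    bg_ge = bg_sorted.size - np.searchsorted(bg_sorted, x, side="left")
    tr_frac = np.where(tr_ge > 0, tr_ge / tr_sorted.size, 1.0 / (2 * tr_sorted.size))
    bg_frac = np.where(bg_ge > 0, bg_ge / bg_sorted.size, 1.0 / (2 * bg_sorted.size))
    out = pd.Series(np.nan, index=scores.index, dtype=float, name=scores.name)
    out.loc[defined.index] = np.log(tr_frac / bg_frac)
    return out


def standardize(metrics: pd.Series | Mapping[str, float]) -> pd.Series:
    """Z-standardise defined values (sample sd, ddof=1); NaN propagates.

    Raises
    ------
    ValueError
        Fewer than 2 defined values, or zero spread (a degenerate feature
        that cannot be standardised).
    """
    s = pd.Series(metrics, dtype=float)
    defined = s.dropna()
    if defined.size < 2:
        raise ValueError("need >= 2 defined values to standardise")
    sd = float(defined.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("degenerate feature: zero spread among defined values")
    return (s - float(defined.mean())) / sd


def compose(scores: pd.DataFrame) -> pd.DataFrame:
    """Append the composite column: mean of available feature scores per gene.

    Genes with no defined feature at all receive a composite of 0 (no
    evidence either way).  The input columns are preserved.
    """
    out = scores.copy()
    composite = out.mean(axis=1, skipna=True)
    out["composite"] = composite.fillna(0.0)
    return out
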