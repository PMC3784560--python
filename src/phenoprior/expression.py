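"""Tissue-expression feature.

Training genes define a tissue contrast: tissues where they are most and
least expressed (on per-gene z-scored values, so absolute expression scale
does not dominate the ranking).  Every gene is then scored by a Welch-type
T statistic contrasting its expression in the high vs low tissue sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TissueContrast", "select_contrast_tissues", "expression_tstat", "tstat_table"]

#: lower bound on the Welch denominator, keeps constant genes finite
VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class TissueContrast:
    high_tissues: frozenset[str]
    low_tissues: frozenset[str]

    def __post_init__(self) -> None:
        if not self.high_tissues or not self.low_tissues:
            raise ValueError("both tissue sets must be non-empty")
        if self.high_tissues & self.low_tissues:
            raise ValueError("high and low tissue sets must be disjoint")


def _zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    sd = sd.where(sd > 0, 1.0)  # constant rows become all-zero z rows
    return values.sub(mu, axis=0).div(sd, axis=0)


def select_contrast_tissues(
    expr: pd.DataFrame,
    training: set[str],
    q: float = 0.1,
    min_per_side: int = 3,
) -> TissueContrast:
    """Pick the tissues where training genes are most / least expressed.

    Tissues are ranked by the mean of training-gene z-scored expression; the
    top and bottom ``max(min_per_side, ceil(q * n_tissues))`` tissues form the
    contrast.  Ties are broken by tissue label so the result is deterministic.

    Parameters
    ----------
    expr
        Genes x tissues matrix (gene symbols as index).  NaN cells allowed.
    """
    if not (0 < q <= 0.5):
        raise ValueError("q must be in (0, 0.5]")
    train = sorted(set(training) & set(expr.index))
    if not train:
        raise ValueError("no training gene present in the expression matrix")
    n_tissues = expr.shape[1]
    n_side = max(min_per_side, math.ceil(q * n_tissues))
    if 2 * n_side > n_tissues:
        raise ValueError(
            f"need {2 * n_side} tissues for a {n_side}-per-side contrast, "
            f"matrix has {n_tissues}"
        )
    tissue_score = _zscore_rows(expr).loc[train].mean(axis=0, skipna=True)
    # one ranking, high from the head and low from the tail, so the sides are
    # disjoint even under ties; secondary sort key (the label) makes it
    # deterministic
    order = tissue_score.to_frame("score")
    order["label"] = order.index.astype(str)
    ranked = order.sort_values(["score", "label"], ascending=[False, True]).index
    high = ranked[:n_side]
    low = ranked[-n_side:]
    return TissueContrast(frozenset(high), frozenset(low))


def _welch(high: np.ndarray, low: np.ndarray) -> float:
    high = high[~np.isnan(high)]
    low = low[~np.isnan(low)]
    if high.size == 0 or low.size == 0:
        return float("nan")
    var_h = float(np.var(high, ddof=1)) if high.size > 1 else 0.0
    var_l = float(np.var(low, ddof=1)) if low.size > 1 else 0.0
    denom = math.sqrt(var_h / high.size + var_l / low.size)
    denom = max(denom, VARIANCE_FLOOR)
    return float((high.mean() - low.mean()) / denom)


def expression_tstat(gene: str, expr: pd.DataFrame, contrast: TissueContrast) -> float:
    """Welch-type statistic for one gene; ``nan`` if the gene is absent."""
    if gene not in expr.index:
        return float("nan")
    row = expr.loc[gene]
    return _welch(
        row[sorted(contrast.high_tissues)].to_numpy(dtype=float),
        row[sorted(contrast.low_tissues)].to_numpy(dtype=float),
    )


def tstat_table(expr: pd.DataFrame, contrast: TissueContrast) -> pd.Series:
    """Welch statistics for every gene in the matrix (vectorised)."""
    high = expr[sorted(contrast.high_tissues)].to_numpy(dtype=float)
    low = expr[sorted(contrast.low_tissues)].to_numpy(dtype=float)

    def _side(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mask = ~np.isnan(x)
        n = mask.sum(axis=1).astype(float)
        total = np.where(mask, x, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = total / n
            dev = np.where(mask, x - mean[:, None], 0.0)
            var = (dev**2).sum(axis=1) / (n - 1)
        var = np.where(n > 1, var, 0.0)
        return mean, var, n

    mh, vh, nh = _side(high)
    ml, vl, nl = _side(low)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(vh / nh + vl / nl)
    denom = np.where(np.isnan(denom), np.nan, np.maximum(denom, VARIANCE_FLOOR))
    t = (mh - ml) / denom
    t = np.where((nh == 0) | (nl == 0), np.nan, t)
    return pd.Series(t, index=expr.index, name="expression")
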