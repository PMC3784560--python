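"""Gamma-Poisson fusion of pathogenicity scores with deletion frequencies.

For each gene the per-subject deletion rate in a background cohort defines a
gamma prior with that mean and variance equal to a constant multiple ``c`` of
the mean (shape = mean/c, rate parameter = 1/c).  For genes with a positive
pathogenicity score, a second, "informed" prior raises the mean by a scaling
factor that grows with the score and shrinks with the background rate (a
common deletion should not be re-weighted much by gene knowledge).  The
evidence for each prior is the gamma-Poisson (negative binomial) marginal
probability of the observed case-cohort deletion count; their ratio, floored
at 1, is the gene's Bayes factor, and the conjugate update under the informed
prior gives the posterior rate distribution.

Genes never observed deleted in the background cohort receive a pseudo-rate:
a fixed fraction (default 1/4) of the lowest nonzero background rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GammaPrior",
    "GeneFrequencyRecord",
    "BayesResult",
    "ScalingConfig",
    "BayesConfig",
    "background_rate",
    "background_rate_table",
    "scaling_factor",
    "calibrate_kappa",
    "log_marginal",
    "marginal_prob",
    "bayes_factor",
    "compute_bayes_factors",
    "rate_per_thousand",
]

#: pseudo-rate in per-subject units: 0.085 deletions per 1000 subjects
DEFAULT_R_STAR = 0.085e-3


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior on a per-subject rate, parameterised by its mean and the
    variance multiple ``c`` (variance = c * mean)."""

    mean: float
    c: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.c <= 0:
            raise ValueError("mean and c must be positive")

    @property
    def shape(self) -> float:
        return self.mean / self.c

    @property
    def rate_param(self) -> float:
        return 1.0 / self.c

    @property
    def variance(self) -> float:
        return self.shape / self.rate_param**2


@dataclass(frozen=True)
class GeneFrequencyRecord:
    """Distinct-subject deletion counts for one gene in two cohorts."""

    gene: str
    k_case: int
    n_case: int
    k_bg: int
    n_bg: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_case <= self.n_case):
            raise ValueError(f"{self.gene}: k_case outside [0, n_case]")
        if not (0 <= self.k_bg <= self.n_bg):
            raise ValueError(f"{self.gene}: k_bg outside [0, n_bg]")


@dataclass(frozen=True)
class ScalingConfig:
    """Family f(s, r) = 1 + kappa * s * r_star / (r_star + r) for s > 0.

    ``kappa`` defaults to the value calibrated so that a unit pathogenicity
    score at a background frequency of ``anchor_rate`` yields
    ``anchor_value`` (a ~4.5-fold rate increase).
    """

    r_star: float = DEFAULT_R_STAR
    kappa: float | None = None
    anchor_score: float = 1.0
    anchor_rate: float = 1.0 / 2940.0
    anchor_value: float = 4.5

    def resolved_kappa(self) -> float:
        if self.kappa is not None:
            return self.kappa
        return calibrate_kappa(
            self.anchor_value, self.anchor_score, self.anchor_rate, self.r_star
        )


@dataclass(frozen=True)
class BayesConfig:
    """All tunables of the Bayes-factor computation.

    ``c`` is the prior variance multiple (variance = c * mean) in
    per-subject-rate units.  The default ``None`` resolves to 1/n_bg, which
    gives the prior exactly the information content of the background cohort
    observation: shape = k_bg and rate parameter = n_bg, i.e. the conjugate
    posterior a flat prior would reach after seeing the background data.
    """

    c: float | None = None
    pseudo_fraction: float = 0.25
    scaling: ScalingConfig = field(default_factory=ScalingConfig)

    def resolved_c(self, n_bg: int) -> float:
        if self.c is not None:
            return self.c
        if n_bg <= 0:
            raise ValueError("n_bg must be positive to resolve the default c")
        return 1.0 / n_bg


@dataclass(frozen=True)
class BayesResult:
    gene: str
    score: float
    background_rate: float
    scaling_factor: float
    prior_bg: GammaPrior
    prior_informed: GammaPrior
    log_marginal_bg: float
    log_marginal_informed: float
    bayes_factor: float  # floored at 1
    bayes_factor_raw: float  # unfloored ratio, diagnostic
    posterior_shape: float
    posterior_rate: float


def background_rate(
    k_bg: int,
    n_bg: int,
    min_nonzero_rate: float | None = None,
    pseudo_fraction: float = 0.25,
) -> float:
    """Observed per-subject background rate, or the pseudo-rate for k_bg = 0.

    ``min_nonzero_rate`` is the smallest nonzero per-subject rate observed
    across all genes in the cohort; it must be supplied when k_bg = 0.
    """
    if n_bg <= 0:
        raise ValueError("n_bg must be positive")
    if k_bg > 0:
        return k_bg / n_bg
    if min_nonzero_rate is None or min_nonzero_rate <= 0:
        raise ValueError(
            "pseudo-rate undefined: no observed nonzero background rate supplied"
        )
    return pseudo_fraction * min_nonzero_rate


def background_rate_table(
    k_bg: pd.Series | np.ndarray, n_bg: int, pseudo_fraction: float = 0.25
) -> pd.Series:
    """Vector version over all genes of a cohort; derives the minimum nonzero
    rate internally.  Raises if no gene was ever observed deleted."""
    k = pd.Series(k_bg, dtype=float)
    if n_bg <= 0:
        raise ValueError("n_bg must be positive")
    if (k < 0).any() or (k > n_bg).any():
        raise ValueError("counts outside [0, n_bg]")
    nonzero = k[k > 0]
    if nonzero.empty:
        raise ValueError("pseudo-rate undefined: no gene with a nonzero count")
    min_rate = float(nonzero.min()) / n_bg
    rates = k / n_bg
    rates[k == 0] = pseudo_fraction * min_rate
    return rates


def calibrate_kappa(
    anchor_value: float = 4.5,
    anchor_score: float = 1.0,
    anchor_rate: float = 1.0 / 2940.0,
    r_star: float = DEFAULT_R_STAR,
) -> float:
    """Solve f(anchor_score, anchor_rate) = anchor_value for kappa."""
    if anchor_value <= 1 or anchor_score <= 0:
        raise ValueError("anchor must describe a >1-fold increase at positive score")
    return (anchor_value - 1.0) * (r_star + anchor_rate) / (anchor_score * r_star)


def scaling_factor(
    score: float,
    bg_rate: float,
    kappa: float | None = None,
    r_star: float = DEFAULT_R_STAR,
) -> float:
    """Prior-mean multiplier: 1 for non-positive scores, otherwise
    1 + kappa * score * r_star / (r_star + bg_rate).

    Increasing in the score and decreasing in the background rate, so gene
    knowledge counts for more when the deletion is rare in controls.
    """
    if bg_rate <= 0:
        raise ValueError("bg_rate must be positive")
    if score <= 0:
        return 1.0
    if kappa is None:
        kappa = calibrate_kappa(r_star=r_star)
    return 1.0 + kappa * score * r_star / (r_star + bg_rate)


def log_marginal(k: int, n: int, prior: GammaPrior) -> float:
    """Log gamma-Poisson marginal of count k among n subjects.

    With shape a and rate parameter b, P(k) = C(a+k-1, k) like negative
    binomial mass: Gamma(a+k)/(Gamma(a) k!) * (b/(b+n))^a * (n/(b+n))^k.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if k < 0:
        raise ValueError("k must be nonnegative")
    a, b = prior.shape, prior.rate_param
    return float(
        gammaln(a + k)
        - gammaln(a)
        - gammaln(k + 1)
        + a * (math.log(b) - math.log(b + n))
        + k * (math.log(n) - math.log(b + n))
    )


def marginal_prob(k: int, n: int, prior: GammaPrior) -> float:
    """Gamma-Poisson marginal probability of the observed count."""
    return math.exp(log_marginal(k, n, prior))


def bayes_factor(
    record: GeneFrequencyRecord,
    score: float,
    bg_rate: float,
    config: BayesConfig | None = None,
) -> BayesResult:
    """Bayes factor and posterior for one gene.

    ``bg_rate`` is the (possibly pseudo-) background per-subject rate; pass
    the output of :func:`background_rate` / :func:`background_rate_table` so
    the cohort-wide minimum rate is honoured.  The posterior is the conjugate
    update of the informed prior by the case count.
    """
    config = config or BayesConfig()
    scal = config.scaling
    c = config.resolved_c(record.n_bg)
    f = scaling_factor(score, bg_rate, scal.resolved_kappa(), scal.r_star)
    prior_bg = GammaPrior(mean=bg_rate, c=c)
    prior_informed = GammaPrior(mean=bg_rate * f, c=c)
    lm_bg = log_marginal(record.k_case, record.n_case, prior_bg)
    lm_inf = log_marginal(record.k_case, record.n_case, prior_informed)
    if not (np.isfinite(lm_bg) and np.isfinite(lm_inf)):
        raise ValueError(f"{record.gene}: degenerate marginal probabilities")
    raw = math.exp(lm_inf - lm_bg)
    return BayesResult(
        gene=record.gene,
        score=score,
        background_rate=bg_rate,
        scaling_factor=f,
        prior_bg=prior_bg,
        prior_informed=prior_informed,
        log_marginal_bg=lm_bg,
        log_marginal_informed=lm_inf,
        bayes_factor=max(1.0, raw),
        bayes_factor_raw=raw,
        posterior_shape=prior_informed.shape + record.k_case,
        posterior_rate=prior_informed.rate_param + record.n_case,
    )


def compute_bayes_factors(
    freq: pd.DataFrame,
    scores: Mapping[str, float] | pd.Series,
    config: BayesConfig | None = None,
) -> pd.DataFrame:
    """Bayes-factor table for every gene in a frequency table.

    Parameters
    ----------
    freq
        DataFrame indexed by gene with columns k_case, n_case, k_bg, n_bg.
    scores
        Composite pathogenicity score per gene; genes absent from the map
        score 0 (no knowledge either way).
    """
    config = config or BayesConfig()
    scores = pd.Series(scores, dtype=float)
    n_bg = int(freq["n_bg"].iloc[0])
    if (freq["n_bg"] != n_bg).any():
        raise ValueError("n_bg must be constant across genes of one cohort")
    rates = background_rate_table(freq["k_bg"], n_bg, config.pseudo_fraction)
    rows = []
    for gene, row in freq.iterrows():
        rec = GeneFrequencyRecord(
            gene=str(gene),
            k_case=int(row["k_case"]),
            n_case=int(row["n_case"]),
            k_bg=int(row["k_bg"]),
            n_bg=int(row["n_bg"]),
        )
        s = float(scores.get(gene, 0.0))
        if math.isnan(s):
            s = 0.0
        res = bayes_factor(rec, s, float(rates.loc[gene]), config)
        rows.append(
            {
                "gene": rec.gene,
                "score": s,
                "k_case": rec.k_case,
                "n_case": rec.n_case,
                "k_bg": rec.k_bg,
                "n_bg": rec.n_bg,
                "case_per_1000": rate_per_thousand(rec.k_case, rec.n_case),
                "bg_per_1000": rate_per_thousand(rec.k_bg, rec.n_bg),
                "background_rate": res.background_rate,
                "scaling_factor": res.scaling_factor,
                "bayes_factor": res.bayes_factor,
                "bayes_factor_raw": res.bayes_factor_raw,
                "posterior_shape": res.posterior_shape,
                "posterior_rate": res.posterior_rate,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def rate_per_thousand(k: int, n: int) -> float:
    """Frequency expressed per 1000 subjects."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 1000.0 * k / n
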