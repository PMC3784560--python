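# Methods

## Problem setting

Given (i) a fixed set of training genes with accepted causal links to a
phenotype, (ii) flat gene-set annotation systems, a gene × tissue expression
matrix and an undirected protein-interaction network, and (iii) per-subject
CNV calls for a case cohort and a background cohort, the package produces:
a composite per-gene pathogenicity score; a per-gene Bayes factor fusing
that score with deletion frequencies; per-subject gene-load statistics; and
a sensitivity/specificity sweep of the "maximum Bayes factor" decision rule.

## Composite pathogenicity score

### Annotation features (category systems)

For each system, a category with `k` of the `K` training genes among its
`n` members over a universe of `N` genes is tested by the one-sided
hypergeometric upper tail `P(X ≥ k)`. A category is *enriched* when
`p ≤ max_p`, the 2×2 odds ratio (Haldane 0.5 correction when any cell is 0)
is `≥ min_odds_ratio`, and `k ≥ min_training`. Defaults: `max_p = 0.01`,
`min_odds_ratio = 2`, `min_training = 2`, configurable per system. A
category equal to the whole universe has an undefined odds ratio and is
excluded with a warning. A gene's raw score is the sum of `−ln p` weights
over the enriched categories containing it: membership in rare, strongly
enriched categories counts for more. Genes outside a system's universe are
*missing*, never zero — absence of evidence is not evidence of absence.

### Expression feature

Tissues are ranked by the mean of training-gene expression after per-gene
z-scoring (so a source's absolute scale cannot dominate; the data give no
normalisation to inherit). The top and bottom `max(3, ⌈q·T⌉)` tissues
(default `q = 0.1`) form the contrast; ties break by tissue label, and both
sides are drawn from a single ranking so they are always disjoint. Each
gene is scored by a Welch statistic `(μ_hi − μ_lo)/√(s²_hi/n_hi + s²_lo/n_lo)`
with the denominator floored at 1e-8 so constant genes score 0, not NaN.
Genes absent from the matrix are missing.

### Interaction feature

Truncated communicability `G = Σ_{k=1..6} Aᵏ/k!` counts walks between two
proteins, down-weighting longer walks; walk length is capped at 6. Walks
(matrix powers), not simple paths, are used — simple-path counting is
NP-hard and the communicability literature is walk-based. The `k = 0`
identity term is excluded (self-communicability is uninformative across
nodes). A gene's raw score sums `G[gene, t]` over training proteins
`t ≠ gene`; a gene's own training membership never inflates its score. No
degree or component normalisation is applied. On large networks the
training columns of the series are computed by iterated sparse
matrix–vector products; the dense matrix is only formed on small graphs.

### Standardisation and fusion

Each feature's raw scores are converted to `ln(frac_train(≥s)/frac_bg(≥s))`
with inclusive comparisons; the index gene counts in the background set (it
is an ordinary gene) and in the training set only if it is a training gene.
Zero tail fractions are floored at `1/(2n)` of the respective set. The
natural log is used; the base is irrelevant after standardisation. The
log-ratios are z-standardised with the sample (n−1) standard deviation;
missing propagates. The composite is the mean of available features, 0 when
all are missing. A degenerate feature (no enriched categories, zero
spread) standardises to all-missing with a warning rather than aborting a
run — `standardize` itself raises, the pipeline catches.

## Bayes model

Counts are distinct subjects with ≥ 1 deletion overlapping the gene, never
calls. The background rate is `k_bg/n_bg`, or the pseudo-rate
`0.25 × (lowest observed nonzero rate)` when `k_bg = 0` (with 1 of 2,940 the
lowest observation this is 0.085 per 1,000 subjects). The background prior
is a gamma with mean `r` and variance `c·r`; the informed prior multiplies
the mean by

```
f(z, r) = 1 + κ · z · r* / (r* + r)    for score z > 0, else 1
```

with `r* = 0.085e-3` per subject and `κ` calibrated at run time so that
`f(1, 1/2940) = 4.5`. This family is ≥ 1, increasing in the score and
decreasing in the background rate, so gene knowledge moves the prior most
for rarely-deleted genes; the anchor pins its scale. The likelihood is
`Poisson(k_case | n_case·ρ)` with `ρ` gamma-distributed, giving the
closed-form gamma–Poisson (negative binomial) marginal

```
P(k) = Γ(a+k)/(Γ(a)·k!) · (b/(b+n))^a · (n/(b+n))^k ,  a = mean/c, b = 1/c,
```

computed in log space. The Bayes factor is `max(1, marginal_informed /
marginal_bg)` (the unfloored ratio is retained for diagnostics); the
posterior under the informed prior is `Gamma(a + k_case, b + n_case)`. For
non-positive scores the two priors coincide and the Bayes factor is exactly 1.

**Variance multiple `c`.** `c` is a single global setting. Its default is
`1/n_bg`, which makes the background prior `Gamma(shape = k_bg, rate =
n_bg)` — precisely the conjugate posterior a flat prior would reach after
observing the background cohort, so the prior carries the information
content of the background data and nothing more. A fixed `c` of order 1
(per-subject-rate units) was rejected: with rates of order 1e-3 it yields
priors whose standard deviation is ~30× their mean, and the marginal
likelihood then barely distinguishes the two prior means, collapsing the
Bayes factor's dynamic range. Any explicit `c` can still be set.

## Cohort analysis

Coordinates are 1-based closed in memory; BED input (0-based half-open) is
converted at parse time — a probe-bounded "minimum interval" is naturally a
closed span. True-positive filters: interval span `end − start <
15,000,000`, `n_probes ≥ 4`, and a type-consistent mean log2 ratio
(deletions `< −0.3`, duplications `> 0.21`; a "deletion" with gain-like
log2 is rejected — the conservative reading of an untyped or-condition).
A gene overlaps a call if they intersect by ≥ 1 base on the same
chromosome. Subject loads: the per-subject maximum composite score among
deleted (or duplicated) genes, optionally excluding training genes; and the
top-3 genes by Bayes factor (> 1 only). Subjects in the case frequency
cohort have their own contribution (0 or 1 per gene, by distinct-subject
counting) removed from `k_case` before their Bayes factors are computed, so
a subject's own deletion cannot inflate their statistic; removing and
re-adding a subject restores the global table exactly. Cohort comparisons
use the unpaired Mann–Whitney rank-sum test — the cohorts are unpaired, so
a signed-rank (paired) test would be inapplicable. Subjects with no
surviving deletion are excluded from deletion-based load comparisons; in
the decision-rule sweep a subject with no gene above BF 1 has max BF = 1 by
definition, sensitivity counts case subjects strictly above the cutoff and
specificity counts non-case subjects at or below it.

## Evaluation

Leave-one-out cross-validation re-runs the *entire* pipeline per held-out
training gene — enrichment, tissue contrast, communicability target set,
tail fractions and standardisation all use the remaining genes — so a
held-out gene's score never touches its own training membership; background
genes are scored once with the full set. Failed folds are reported, never
silently skipped. ROC curves group tied scores into one threshold and AUC
is the trapezoid area, equal to the positive-outranks-negative probability.

## Synthetic data generator

The generator emulates the structure the method assumes: training genes
over-represented in designated categories (membership probability =
base rate × odds multiplier, default 12), elevated in designated tissues
(additive effect 2.0 on noise sd 1.0), preferentially interconnected
(extra edge probability 0.15 over a 0.01 baseline), 10% of genes missing
per source, and genes laid out on a synthetic genome (40 kb genes, 20 kb
gaps) so extended deletion events span neighbours. Cohorts follow a
baseline per-subject per-gene deletion rate of 0.5/1000 with 2,000 subjects
per arm; five planted risk genes (a deterministic subset of the training
set) are deleted at 20× baseline in case subjects only, and a tenth of
calls are corrupted to violate exactly one filter rule each. Default sizes
(800 genes, 30 training genes, 4 systems × 40 categories, 20 tissues) are
the package's desk-scale study conditions; genome-scale inputs (~20k genes,
dozens of training genes) only grow the same computations. Three
pseudo-random streams (knowledge, network, cohorts) spawn from the master
seed, so regenerating one input leaves the others untouched.

What passing tests on these data do **not** show: real annotation systems
have ontology structure and hugely skewed category sizes; real CNV
architecture has recurrent, repeat-mediated events, probe-density
artifacts, and sex-chromosome effects; real expression is not homoscedastic
Gaussian. Synthetic recovery demonstrates correctness of the machinery and
calibration of the statistics, not field performance.

## Numerical choices and degenerate inputs

- Enrichment p-values floored at 1e-300 so weights stay finite.
- Tail-fraction floors `1/(2n)`; variance floor 1e-8 in the Welch
  denominator; all marginal probabilities in log space.
- Ties: tissue ranking breaks by label; ROC groups tied scores; top-gene
  lists break Bayes-factor ties by gene symbol.
- Empty training∩universe, all-zero background counts, and leave-one-out
  decrements below zero raise immediately — they indicate broken inputs,
  not edge cases to paper over.

## Limitations

- The exact scaling-function family and the annotation match-score formula
  are this package's own constructions satisfying the documented
  qualitative properties and the single quantitative anchor; other
  functional forms meeting the same constraints would give different
  absolute Bayes factors (rankings are far less sensitive).
- Enrichment treats annotation systems as flat sets; no parent-term
  propagation.
- The deletion Bayes model has no duplication counterpart; duplications
  participate only in score-based load statistics.
- No sex-aware copy-number handling on X; no confidence-weighted network
  edges.
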