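"""Per-subject gene load and the decision-rule sweep on a synthetic cohort.

Simulates case and background cohorts whose case subjects delete five
planted risk genes at 20x the baseline rate, filters the calls, computes
leave-one-subject-out Bayes factors per subject, compares the cohorts'
maximum Bayes factors with a rank-sum test, and reports the operating point
of the "max BF > 1" decision rule.
"""

from phenoprior import (
    SimulationConfig,
    compare_cohorts,
    decision_rule_sweep,
    run_study,
    simulate_study,
)

study = simulate_study(SimulationConfig(seed=7))
results = run_study(
    study.bundle,
    study.training,
    study.calls,
    study.gene_models,
    study.config.n_case,
    study.config.n_background,
)

case = [l.max_bayes_factor for l in results.loads if l.cohort == "case"]
background = [l.max_bayes_factor for l in results.loads if l.cohort != "case"]
stat, p = compare_cohorts(case, background, alternative="greater")
print(f"subjects with surviving deletions: {len(case)} case, {len(background)} background")
print(f"rank-sum test of max Bayes factors (case > background): p = {p:.2e}")

point = next(pt for pt in decision_rule_sweep(results.loads, cutoffs=[1.0]))
print(
    f"decision rule 'max BF > 1': sensitivity {point.sensitivity:.2f}, "
    f"specificity {point.specificity:.2f}"
)
print(
    "\nCase subjects carry deletions of high-scoring risk genes, so their "
    "maximum Bayes factor distribution dominates the background cohort's; "
    "the leave-one-subject-out correction keeps each subject's own deletion "
    "from inflating their statistic."
)
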