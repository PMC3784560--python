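"""Bayes factors from pathogenicity scores plus deletion frequencies.

Builds a small per-gene frequency table by hand (case cohort of 1,616
subjects, background cohort of 2,940 -- the situation a diagnostic
laboratory would extract from its CNV database) and fuses it with composite
scores.  Genes deleted more often in cases than the background-informed
prior expects, and with a positive score, earn Bayes factors above 1.
"""

import pandas as pd

from phenoprior import compute_bayes_factors

freq = pd.DataFrame(
    {
        "k_case": [6, 13, 10, 2, 0],  # distinct case subjects with a deletion
        "n_case": [1616] * 5,
        "k_bg": [1, 13, 7, 0, 0],  # distinct background subjects
        "n_bg": [2940] * 5,
    },
    index=pd.Index(["geneA", "geneB", "geneC", "geneD", "geneE"], name="gene"),
)
scores = pd.Series(
    {"geneA": 2.49, "geneB": 2.22, "geneC": 0.98, "geneD": 2.47, "geneE": -0.4}
)

table = compute_bayes_factors(freq, scores)
cols = ["score", "scaling_factor", "case_per_1000", "bg_per_1000", "bayes_factor"]
print(table[cols].round(2).to_string())

print(
    "\ngeneA: rare in the background (0.34/1000) but deleted in 6 cases -> "
    "a large Bayes factor.\n"
    "geneD: never seen in the background, so its prior mean is the pseudo-rate "
    "(0.085/1000) and two case deletions already count heavily.\n"
    "geneE: negative score, so informed and background priors coincide and "
    "the Bayes factor is 1 by definition."
)
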