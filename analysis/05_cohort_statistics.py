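#!/usr/bin/env python
"""Genotype–phenotype statistics on synthetic cohorts.

Builds synthetic per-individual cohorts configured to the published group
summaries (stand-ins for tables that are not deposited in per-individual
form) and runs the study's statistics: Mann–Whitney U contrasts of the
homozygote groups, percent median reductions, and the allele-dosage R² with
permutation inference.

Cohorts (Hardy–Weinberg genotype counts at duplication allele frequency
0.406):
  * hepatic protein expression, n = 73, medians 6.04 (WT/WT) vs 3.91
    (dup/dup) — a 35% reduction;
  * hepatic mRNA expression, n = 73, medians 0.026 vs 0.014 — a 46-47%
    reduction;
  * sumatriptan AUC, n = 40, where the ~14% mean shift stays
    non-significant at realistic pharmacokinetic variability.

Writes results/cohort_statistics.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import oct1splice as o
from oct1splice.cohort import hwe_genotype_counts

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 73
MAF = 0.406

COHORTS = [
    # name, n, wt median, hom-median reduction, log-sd, units
    ("protein_expression", 73, 6.04, 1 - 3.91 / 6.04, 0.55, "a.u."),
    ("mrna_expression", 73, 0.026, 1 - 0.014 / 0.026, 0.80, "per b-actin"),
    ("sumatriptan_auc", 40, 6277.0, 1 - 7187.0 / 6277.0, 0.40, "min*ng/ml"),
]


def main() -> None:
    rows = []
    for i, (name, n, med_wt, reduction, sigma, units) in enumerate(COHORTS):
        counts = hwe_genotype_counts(n, MAF)
        df = o.simulate_cohort(counts, med_wt, max(reduction, 0.0),
                               sigma_log=sigma, seed=SEED + i)
        if reduction < 0:
            # an AUC *increase* in duplication homozygotes: apply inverse
            df.loc[df.genotype == "dup/dup", "phenotype"] *= (1 - reduction)
            df.loc[df.genotype == "WT/dup", "phenotype"] *= np.sqrt(
                1 - reduction)
        wt = df.loc[df.genotype == "WT/WT", "phenotype"]
        dup = df.loc[df.genotype == "dup/dup", "phenotype"]
        u, p = o.mann_whitney(dup, wt)
        red = o.median_reduction(dup, wt)
        ve = o.variance_explained(df, "phenotype", seed=SEED + i)
        rows.append({"cohort": name, "units": units, "n": n,
                     "n_wt": len(wt), "n_dup": len(dup),
                     "median_wt": red.median_wt, "median_dup": red.median_dup,
                     "median_reduction_pct": red.percent,
                     "mann_whitney_U": u, "p_value": p,
                     "r_squared": ve.r_squared,
                     "p_permutation": ve.p_permutation})
    res = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    res.to_csv(OUT / "cohort_statistics.tsv", sep="\t", index=False,
               float_format="%.5g")
    print(res.to_string(index=False))
    print("\nExpression cohorts show significant homozygote contrasts with "
          "median reductions near the configured 35%/46% targets but only a "
          "small share of total variability explained; the AUC contrast "
          "stays non-significant.")


if __name__ == "__main__":
    main()
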