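#!/usr/bin/env python
"""Surviving alternative-transcript levels in liver by genotype.

Simulates liver RNA amplicon libraries for the three duplication genotypes.
Decay removes nearly all alternative transcripts, so the surviving
alternative fraction is small even though roughly 29% of duplication-allele
transcripts are mis-spliced: the homozygous group is configured to the
published 0.58% group mean (decay solved accordingly), heterozygotes carry
half the duplication dose, and wild-type homozygotes can only splice
correctly.

Writes results/liver_splicing_by_genotype.tsv.
"""

from pathlib import Path

import pandas as pd

import oct1splice as o
from oct1splice.defaults import (HOM_ALT_FRACTION, LIVER_DECAY,
                                 LIVER_MIS_SPLICE)
from oct1splice.refmodel import LIVER, make_default_locus

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 35854239 % 2 ** 31
DEPTH = 20_000


def main() -> None:
    locus = make_default_locus()
    anchors = o.build_anchors(locus)
    d_hom = o.solve_decay_for_alt_frac(LIVER_MIS_SPLICE, HOM_ALT_FRACTION,
                                       "dup/dup")
    scenarios = [
        ("liver_wt", "WT/WT", 0.0, 0.0),
        ("liver_het", "WT/dup", LIVER_MIS_SPLICE, LIVER_DECAY),
        ("liver_hom", "dup/dup", LIVER_MIS_SPLICE, d_hom),
    ]
    rows = []
    for i, (sid, genotype, m, d) in enumerate(scenarios):
        spec = o.SampleSpec(sid, genotype, LIVER, depth=DEPTH,
                            mis_splice_prob=m, decay_prob=d,
                            error_rate=0.001, seed=SEED + i)
        counts, _ = o.run_sample(locus, spec, anchors)
        sq = o.splice_fraction(counts)
        exp = (0.0 if genotype == "WT/WT"
               else float(o.forward_alt_fraction(m, d, genotype)))
        rows.append({"sample_id": sid, "genotype": genotype,
                     "pct_alternative": 100 * (1 - sq.f_correct),
                     "expected_pct": 100 * exp,
                     "ci_lo": 100 * (1 - sq.ci95[1]),
                     "ci_hi": 100 * (1 - sq.ci95[0]),
                     "n_classified": sq.n_classified})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "liver_splicing_by_genotype.tsv", sep="\t", index=False,
              float_format="%.4f")
    print(df.to_string(index=False))
    print("\nDespite ~29% mis-splicing of duplication-allele transcripts, "
          "decay leaves well under 1% alternative reads in every genotype.")


if __name__ == "__main__":
    main()
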