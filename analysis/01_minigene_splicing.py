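#!/usr/bin/env python
"""Minigene splicing assay, in silico.

Simulates reporter-minigene amplicon libraries for the wild-type and
duplication alleles (reporter transcripts escape decay, so only mis-splicing
acts), runs them through merge → classify → quantify, and tabulates the
percentage of correctly spliced transcripts per sample. The duplication
allele is expected near 62% correct at the deep-sequencing point estimate;
the wild-type allele has a single donor and must be ~100% correct.

Writes results/minigene_splice_fractions.tsv.
"""

from pathlib import Path

import pandas as pd

import oct1splice as o
from oct1splice.defaults import MINIGENE_DEPTH, MINIGENE_MIS_SPLICE
from oct1splice.refmodel import MINIGENE, make_default_locus

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20210507
DEPTH = 20_000   # desk-scale depth; study-scale runs live in the acceptance
                 # script


def main() -> None:
    locus = make_default_locus()
    anchors = o.build_anchors(locus)
    rows = []
    scenarios = [
        ("minigene_wt", "WT/WT", 0.0),
        ("minigene_dup_clone1", "dup/dup", MINIGENE_MIS_SPLICE),
        ("minigene_dup_clone2", "dup/dup", MINIGENE_MIS_SPLICE),
    ]
    for i, (sid, genotype, m) in enumerate(scenarios):
        spec = o.SampleSpec(sid, genotype, MINIGENE, depth=DEPTH,
                            mis_splice_prob=m, error_rate=0.003,
                            seed=SEED + i)
        counts, qc = o.run_sample(locus, spec, anchors)
        sq = o.splice_fraction(counts)
        rows.append({"sample_id": sid, "genotype": genotype,
                     "true_mis_splice_prob": m,
                     "pct_correct": 100 * sq.f_correct,
                     "ci_lo": 100 * sq.ci95[0], "ci_hi": 100 * sq.ci95[1],
                     "n_classified": sq.n_classified,
                     "merge_rate": qc["merge_rate"]})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "minigene_splice_fractions.tsv", sep="\t", index=False,
              float_format="%.4f")
    print(df.to_string(index=False))
    print("\nDuplication-allele clones sit near 62% correctly spliced; the "
          "wild-type minigene is fully correct apart from read-error noise.")


if __name__ == "__main__":
    main()
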