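#!/usr/bin/env python
"""Liver allelic expression imbalance and decay inversion.

Simulates nine heterozygous liver donors, each with a genomic-DNA amplicon
library and an RNA (cDNA) library at the published mis-splicing/decay point
estimates (m = 0.287, d = 0.961). Per donor the A-allele fraction is
estimated on DNA (expectation 50%) and RNA (expectation 42%); the paired
t-test quantifies the imbalance, and the closed-form inversion recovers
(m, d) from the pooled RNA observations. The correct-read A/G ratio
(expectation 71.3%) provides the second, ratio-based mis-splicing estimator.

Writes results/liver_aei.tsv and results/nmd_estimates.json.
"""

import json
from pathlib import Path

import pandas as pd

import oct1splice as o
from oct1splice.defaults import LIVER_DECAY, LIVER_MIS_SPLICE
from oct1splice.refmodel import GENOMIC, LIVER, make_default_locus

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 628031
N_DONORS = 9
DEPTH = 12_000   # per-library desk-scale depth (study mean is 74,326;
                 # study-scale single samples run in the acceptance script)


def main() -> None:
    locus = make_default_locus()
    anchors = o.build_anchors(locus)
    rows, pairs = [], []
    pooled_alt = pooled_spliced = pooled_cor_a = pooled_cor_g = 0
    for i in range(N_DONORS):
        dna_spec = o.SampleSpec(f"donor{i}_dna", "WT/dup", GENOMIC,
                                depth=DEPTH, error_rate=0.003,
                                seed=SEED + 2 * i)
        rna_spec = o.SampleSpec(f"donor{i}_rna", "WT/dup", LIVER,
                                depth=DEPTH,
                                mis_splice_prob=LIVER_MIS_SPLICE,
                                decay_prob=LIVER_DECAY, error_rate=0.003,
                                seed=SEED + 2 * i + 1)
        dna_ct, _ = o.run_sample(locus, dna_spec, anchors)
        rna_ct, _ = o.run_sample(locus, rna_spec, anchors)
        f_dna = o.allele_fraction(dna_ct).f_A
        f_rna = o.allele_fraction(rna_ct).f_A
        pairs.append((f_dna, f_rna))
        pooled_alt += rna_ct.n(splice="alternative")
        pooled_spliced += (rna_ct.n(splice="correct")
                           + rna_ct.n(splice="alternative"))
        pooled_cor_a += rna_ct.n(splice="correct", allele="A")
        pooled_cor_g += rna_ct.n(splice="correct", allele="G")
        rows.append({"donor": f"donor{i}", "f_A_DNA": f_dna,
                     "f_A_RNA": f_rna,
                     "alt_frac_RNA": 1 - o.splice_fraction(rna_ct).f_correct})

    df = pd.DataFrame(rows)
    aei = o.aei_test(pairs)
    alt_frac = pooled_alt / pooled_spliced
    inv = o.nmd_invert(aei.f_A_RNA, alt_frac)
    ratio = pooled_cor_a / pooled_cor_g
    from_ratio = o.nmd_from_ratio(ratio, md=inv.md)

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "liver_aei.tsv", sep="\t", index=False,
              float_format="%.5f")
    payload = {
        "aei": {"f_A_DNA": aei.f_A_DNA, "f_A_RNA": aei.f_A_RNA,
                "t_stat": aei.t_stat, "p_value": aei.p_value,
                "n_samples": aei.n_samples},
        "pooled_alt_fraction_RNA": alt_frac,
        "correct_read_A_over_G_ratio": ratio,
        "inversion_from_allele_fraction": {"md": inv.md, "m": inv.m,
                                           "d": inv.d},
        "inversion_from_ratio": {"m": from_ratio.m, "d": from_ratio.d},
        "true_parameters": {"m": LIVER_MIS_SPLICE, "d": LIVER_DECAY},
    }
    (OUT / "nmd_estimates.json").write_text(json.dumps(payload, indent=2)
                                            + "\n")
    print(df.to_string(index=False))
    print(json.dumps(payload, indent=2))
    print(f"\nRNA A-allele fraction {100 * aei.f_A_RNA:.1f}% vs DNA "
          f"{100 * aei.f_A_DNA:.1f}% (paired t-test p = {aei.p_value:.2e}); "
          f"inversion recovers m = {inv.m:.3f}, d = {inv.d:.3f} against "
          f"generative truth m = {LIVER_MIS_SPLICE}, d = {LIVER_DECAY}.")


if __name__ == "__main__":
    main()
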