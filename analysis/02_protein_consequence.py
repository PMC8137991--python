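#!/usr/bin/env python
"""Protein consequence of the retained 8 bp duplication.

The alternative transcript keeps the 8 duplicated intron bases in the open
reading frame, shifting it and producing a premature stop. The real
transporter CDS is not distributed with the package, so this driver builds a
synthetic 554-codon CDS engineered to reproduce the event geometry: the
insertion lands after codon 425 and the shifted frame reaches a stop after
seven novel residues, truncating the 554-residue protein to 432 codons'
worth of message (last translated residue 432, stop at codon position 433
in the mutant frame).

Writes results/protein_consequence.json.
"""

import itertools
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from oct1splice.refmodel import frameshift_consequence

OUT = Path(__file__).resolve().parents[1] / "results"
N_CODONS = 554        # transporter length in residues
INS_AFTER_CODON = 425
INSERTION = "GTAAGTTG"  # duplicated donor head retained in the mRNA
NOVEL_TARGET = 7


def synthetic_cds(seed: int = 408) -> str:
    """Synthetic stand-in CDS (labelled synthetic; the real CDS is not
    shipped) whose shifted frame hits a stop after exactly 7 novel codons."""
    rng = np.random.default_rng(seed)
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    safe = [c for c in codons if str(Seq(c).translate()) != "*"
            and c != "ATG"]
    while True:
        body = rng.choice(safe, size=N_CODONS - 1)
        cds = "ATG" + "".join(body) + "TAA"
        res = frameshift_consequence(cds, 3 * INS_AFTER_CODON, INSERTION)
        if (res.premature_stop
                and res.last_reference_codon == INS_AFTER_CODON
                and res.novel_residue_count == NOVEL_TARGET):
            return cds


def main() -> None:
    cds = synthetic_cds()
    res = frameshift_consequence(cds, 3 * INS_AFTER_CODON, INSERTION)
    payload = {"insertion": INSERTION,
               "insertion_after_codon": INS_AFTER_CODON,
               "cds_codons": N_CODONS,
               "consequence": {**asdict(res), "flags": list(res.flags)}}
    OUT.mkdir(exist_ok=True)
    (OUT / "protein_consequence.json").write_text(
        json.dumps(payload, indent=2) + "\n")
    print(json.dumps(payload, indent=2))
    print(f"\nReading frame intact through codon {res.last_reference_codon}, "
          f"then {res.novel_residue_count} novel residues before a stop at "
          f"mutant codon {res.stop_codon_index}: the protein is truncated "
          f"from {N_CODONS} to {res.truncated_length} residues.")


if __name__ == "__main__":
    main()
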