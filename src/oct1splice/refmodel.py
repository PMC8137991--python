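"""Reference model of the SLC22A1 exon 7 / intron 7 locus.

The studied variant is an 8 bp duplication of the 5' head of intron 7,
including the canonical GT splice donor, immediately downstream of exon 7.
The duplicated donor can be used instead of the original one, in which case
the mature transcript retains the 8 duplicated bases, shifting the reading
frame. Exon 7 also carries the Met408Val SNP (rs628031, A/G), which is the
readable marker used for allele-specific read counting.

This module holds the locus description, builds haplotype- and
isoform-specific reference sequences for the three amplicon contexts
(minigene cDNA, liver cDNA, genomic DNA), and computes the protein
consequence of a frame-shifting insertion.

Coordinates are 0-based, half-open throughout. ``junction_pos`` is the index
of the first base after exon 7's contribution to the sequence: the first
exon 8 base for cDNA isoforms, the first intronic base for genomic amplicons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .defaults import DUP_LEN

# Context / splice labels used across the package.
MINIGENE = "minigene_cDNA"
LIVER = "liver_cDNA"
GENOMIC = "genomic_DNA"
CORRECT = "correct"
ALTERNATIVE = "alternative"
NA = "na"

_DNA = set("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return str(Seq(seq).reverse_complement())


def _check_dna(seq: str, name: str) -> None:
    if not set(seq) <= _DNA:
        raise ValueError(f"{name} contains non-ACGT characters")


@dataclass(frozen=True)
class LocusModel:
    """Sequences and coordinates of the amplified region.

    ``dup_seq`` is by definition the first ``dup_len`` bases of intron 7 —
    the duplication is a tandem copy of the intron head, so the duplicated
    donor is sequence-identical to the original one.
    """

    exon7_seq: str
    intron7_seq: str
    exon8_seq: str
    dup_len: int = DUP_LEN
    snp_offset: int = 0          # 0-based position of rs628031 within exon 7
    snp_alleles: tuple[str, str] = ("A", "G")
    # Optional heterologous reporter-exon tails flanking the minigene amplicon.
    minigene_flank5: str = ""
    minigene_flank3: str = ""

    def __post_init__(self) -> None:
        for nm in ("exon7_seq", "intron7_seq", "exon8_seq",
                   "minigene_flank5", "minigene_flank3"):
            _check_dna(getattr(self, nm), nm)
        if self.dup_len <= 0:
            raise ValueError("dup_len must be positive")
        if self.dup_len > len(self.intron7_seq):
            raise ValueError("dup_len exceeds intron length")
        if not self.intron7_seq.startswith("GT"):
            raise ValueError("intron 7 must start with the canonical GT donor")
        if not 0 <= self.snp_offset < len(self.exon7_seq):
            raise ValueError("snp_offset outside exon 7")
        if set(self.snp_alleles) - _DNA or len(self.snp_alleles) != 2:
            raise ValueError("snp_alleles must be two DNA bases")

    @property
    def dup_seq(self) -> str:
        return self.intron7_seq[: self.dup_len]


@dataclass(frozen=True)
class Haplotype:
    """One chromosome: duplication status plus the linked rs628031 base.

    In the population the duplication travels almost exclusively with the
    Met408 A allele (r^2 ≈ 0.95); the simulator enforces that linkage by
    default via :func:`Haplotype.from_linkage`, but the type itself allows
    any combination so that linkage-broken haplotypes can be represented.
    """

    dup_allele: bool
    met408_allele: str = "A"

    def __post_init__(self) -> None:
        if self.met408_allele not in _DNA:
            raise ValueError("met408_allele must be a DNA base")

    @classmethod
    def from_linkage(cls, dup_allele: bool) -> "Haplotype":
        """Completely linked haplotype: duplication <=> Met408 A allele."""
        return cls(dup_allele=dup_allele,
                   met408_allele="A" if dup_allele else "G")


@dataclass(frozen=True)
class IsoformSeq:
    haplotype: Haplotype
    context: str
    splice: str
    seq: str
    junction_pos: int


def build_isoform(locus: LocusModel, hap: Haplotype, context: str,
                  splice: str) -> IsoformSeq:
    """Haplotype- and isoform-specific amplicon reference sequence.

    cDNA contexts: ``correct`` = exon7 + exon8; ``alternative`` = exon7 +
    duplicated intron head + exon8 (only producible from a duplication
    haplotype — the wild-type allele has a single donor). Genomic context:
    exon7 + (duplication if present) + intron head; splice must be ``na``.
    The rs628031 base is substituted at the SNP offset.
    """
    if context not in (MINIGENE, LIVER, GENOMIC):
        raise ValueError(f"unknown context {context!r}")
    exon7 = (locus.exon7_seq[: locus.snp_offset]
             + hap.met408_allele
             + locus.exon7_seq[locus.snp_offset + 1:])
    if context == GENOMIC:
        if splice != NA:
            raise ValueError("genomic context has no splice status; use 'na'")
        insert = locus.dup_seq if hap.dup_allele else ""
        seq = exon7 + insert + locus.intron7_seq
        junction = len(exon7)
        return IsoformSeq(hap, context, NA, seq, junction)

    if splice == CORRECT:
        core = exon7 + locus.exon8_seq
        junction = len(exon7)
    elif splice == ALTERNATIVE:
        if not hap.dup_allele:
            raise ValueError("isoform not producible: wild-type haplotype "
                             "has no alternative donor")
        core = exon7 + locus.dup_seq + locus.exon8_seq
        junction = len(exon7) + locus.dup_len
    else:
        raise ValueError(f"unknown splice status {splice!r}")

    if context == MINIGENE:
        seq = locus.minigene_flank5 + core + locus.minigene_flank3
        junction += len(locus.minigene_flank5)
    else:
        seq = core
    return IsoformSeq(hap, context, splice, seq, junction)


# ---------------------------------------------------------------------------
# Protein consequence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinConsequence:
    """Consequence of an insertion for the translated protein.

    ``last_reference_codon`` counts the leading codons whose translation is
    identical to wild type; ``novel_residue_count`` counts residues after
    that point up to (exclusive) the first stop in the mutant frame. When a
    stop exists, ``truncated_length = last_reference_codon +
    novel_residue_count`` and ``stop_codon_index = truncated_length + 1``
    (1-based, mutant frame). The literature describes this event with two
    off-by-one conventions (altered sequence "after codon X followed by a
    premature stop after k residues" vs naming the last residue before the
    stop); all fields are reported so either convention can be read off.
    """

    last_reference_codon: int
    novel_residue_count: int
    truncated_length: int
    stop_codon_index: int | None
    premature_stop: bool
    flags: tuple[str, ...] = ()


def frameshift_consequence(cds: str, insertion_pos: int,
                           insertion_seq: str) -> ProteinConsequence:
    """Translate a CDS with an insertion and report the protein consequence.

    ``cds`` must be a complete ORF (length divisible by 3, start codon,
    terminal stop). The insertion is placed at ``insertion_pos`` (0-based,
    between bases). Standard genetic code.
    """
    _check_dna(cds, "cds")
    _check_dna(insertion_seq, "insertion_seq")
    if len(cds) % 3 != 0:
        raise ValueError("cds length must be divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("cds must start with ATG")
    if str(Seq(cds[-3:]).translate()) != "*":
        raise ValueError("cds must end with a stop codon")
    if not 0 <= insertion_pos <= len(cds):
        raise ValueError("insertion_pos outside cds")

    wt_prot = str(Seq(cds).translate())
    wt_prot = wt_prot[: wt_prot.index("*")]

    if len(insertion_seq) == 0:
        return ProteinConsequence(
            last_reference_codon=len(wt_prot), novel_residue_count=0,
            truncated_length=len(wt_prot), stop_codon_index=len(wt_prot) + 1,
            premature_stop=False, flags=("synonymous-length event",))

    mutant = cds[:insertion_pos] + insertion_seq + cds[insertion_pos:]
    mut_trans = str(Seq(mutant[: len(mutant) - len(mutant) % 3]).translate())
    stop_at = mut_trans.find("*")
    mut_prot = mut_trans if stop_at < 0 else mut_trans[:stop_at]

    last_ref = 0
    for a, b in zip(mut_prot, wt_prot):
        if a != b:
            break
        last_ref += 1
    novel = len(mut_prot) - last_ref

    in_frame = len(insertion_seq) % 3 == 0
    expected_full = len(wt_prot) + (len(insertion_seq) // 3 if in_frame else 0)
    flags: list[str] = []
    if stop_at < 0:
        flags.append("no premature stop")
        premature = False
        stop_idx = None
    else:
        premature = len(mut_prot) < expected_full if in_frame else True
        if not premature:
            flags.append("no premature stop")
        stop_idx = len(mut_prot) + 1
    return ProteinConsequence(
        last_reference_codon=last_ref, novel_residue_count=novel,
        truncated_length=len(mut_prot), stop_codon_index=stop_idx,
        premature_stop=premature, flags=tuple(flags))


# ---------------------------------------------------------------------------
# Shipped loci and I/O
# ---------------------------------------------------------------------------

def make_toy_locus() -> LocusModel:
    """Tiny hand-checkable locus used in examples and unit tests."""
    return LocusModel(exon7_seq="ACGTACGTAC", intron7_seq="GTAAGTTGCC",
                      exon8_seq="TTGGCCAA", dup_len=8, snp_offset=2)


_DEFAULT_LOCUS_SEED = 660731  # fixed; the shipped locus is deterministic


def make_default_locus() -> LocusModel:
    """Deterministic synthetic stand-in for the real locus.

    The published study never prints the amplicon sequences, so the package
    ships a synthetic locus with the real locus's architecture: a 180 bp
    exon 7 with the SNP at offset 100, an intron 7 whose head begins with
    the canonical GTAAGT donor, a 120 bp exon 8, and 40 bp reporter-exon
    flanks for the minigene context. A user-supplied real locus (FASTA +
    JSON sidecar) can be used instead via :func:`load_locus`.
    """
    rng = np.random.default_rng(_DEFAULT_LOCUS_SEED)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def rand(n: int) -> str:
        return rng.choice(bases, size=n).tobytes().decode()

    exon7 = rand(180)
    intron7 = "GTAAGT" + rand(54)
    exon8 = rand(120)
    return LocusModel(exon7_seq=exon7, intron7_seq=intron7, exon8_seq=exon8,
                      dup_len=DUP_LEN, snp_offset=100,
                      minigene_flank5=rand(40), minigene_flank3=rand(40))


def write_locus(locus: LocusModel, fasta_path: str | Path,
                json_path: str | Path) -> None:
    """Write the locus as a multi-record FASTA plus a JSON coordinate sidecar."""
    recs = [SeqRecord(Seq(locus.exon7_seq), id="exon7", description=""),
            SeqRecord(Seq(locus.intron7_seq), id="intron7", description=""),
            SeqRecord(Seq(locus.exon8_seq), id="exon8", description="")]
    if locus.minigene_flank5:
        recs.append(SeqRecord(Seq(locus.minigene_flank5), id="minigene_flank5",
                              description=""))
    if locus.minigene_flank3:
        recs.append(SeqRecord(Seq(locus.minigene_flank3), id="minigene_flank3",
                              description=""))
    SeqIO.write(recs, str(fasta_path), "fasta")
    meta = {"dup_len": locus.dup_len, "snp_offset": locus.snp_offset,
            "snp_alleles": list(locus.snp_alleles)}
    Path(json_path).write_text(json.dumps(meta, indent=2) + "\n")


def load_locus(fasta_path: str | Path, json_path: str | Path) -> LocusModel:
    segs = {r.id: str(r.seq).upper()
            for r in SeqIO.parse(str(fasta_path), "fasta")}
    for need in ("exon7", "intron7", "exon8"):
        if need not in segs:
            raise ValueError(f"locus FASTA is missing record {need!r}")
    meta = json.loads(Path(json_path).read_text())
    return LocusModel(exon7_seq=segs["exon7"], intron7_seq=segs["intron7"],
                      exon8_seq=segs["exon8"], dup_len=int(meta["dup_len"]),
                      snp_offset=int(meta["snp_offset"]),
                      snp_alleles=tuple(meta.get("snp_alleles", ("A", "G"))),
                      minigene_flank5=segs.get("minigene_flank5", ""),
                      minigene_flank3=segs.get("minigene_flank3", ""))


def isoform_to_record(iso: IsoformSeq) -> SeqRecord:
    name = (f"{iso.context}|{iso.splice}|dup={int(iso.haplotype.dup_allele)}"
            f"|met408={iso.haplotype.met408_allele}")
    return SeqRecord(Seq(iso.seq), id=name,
                     description=f"junction_pos={iso.junction_pos}")
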