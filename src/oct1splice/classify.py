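"""Joint splice-isoform and SNP-allele calling from merged amplicon reads.

The only sequence difference between the correctly spliced and the
alternative transcript is a fixed 8 bp insertion at a known junction, so a
full alignment is unnecessary: short k-mer *anchors* spanning the diagnostic
boundaries decide the call. The correct isoform is diagnosed by the k-mer
spanning exon7|exon8; the alternative isoform by the k-mers spanning
exon7|duplication and duplication|exon8. The rs628031 allele is read at the
wildcarded centre of a k-mer anchored in exon 7. Matching is Hamming-based
with at most ``max_mismatch`` substitutions.

Because the insertion is a tandem copy of the adjacent intron head, a poorly
chosen k can make the correct and alternative anchors collide; anchor
construction verifies uniqueness and refuses ambiguous anchor sets.

Reads matching both isoform anchor sets, or neither, are reported as
unclassified — never silently assigned. Genomic DNA reads contain no spliced
junction and come out splice-unclassified by design; their duplication
status is inferred downstream through the linked SNP allele, exactly as the
allelic-expression-imbalance design does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import refmodel as rm
from .defaults import DEFAULT_ANCHOR_K, DEFAULT_MAX_MISMATCH

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class AnchorSet:
    correct_anchor: str
    alt_anchors: tuple[str, ...]
    snp_anchor: str            # wildcard base 'N' at snp position
    snp_wild_idx: int
    snp_alleles: tuple[str, str]
    k: int
    max_mismatch: int
    # k-mer strictly inside intron 7 beyond the duplicated head: present in
    # genomic amplicons of either allele, absent from spliced transcripts.
    # Distinguishes unspliced junctions (call 'na') from the alternative
    # transcript, whose exon7|duplication anchor a genomic junction would
    # otherwise mimic. None when the intron is too short at the chosen k.
    intron_anchor: str | None = None


def _anchor_at(seq: str, junction: int, half: int) -> str:
    if junction - half < 0 or junction + half > len(seq):
        raise ValueError("junction too close to the sequence edge for this k")
    return seq[junction - half: junction + half]


def build_anchors(locus: rm.LocusModel, k: int = DEFAULT_ANCHOR_K,
                  max_mismatch: int = DEFAULT_MAX_MISMATCH) -> AnchorSet:
    """Construct and validate the diagnostic anchor set for a locus.

    Raises if the tandem-duplication geometry (or any sequence coincidence)
    makes an anchor ambiguous at the chosen k; the caller should increase k.
    """
    if k % 2 != 0 or not 8 <= k <= 40:
        raise ValueError("k must be even and within [8, 40]")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    half = k // 2
    e7, dup, e8 = locus.exon7_seq, locus.dup_seq, locus.exon8_seq

    correct_core = e7 + e8
    alt_core = e7 + dup + e8
    correct_anchor = _anchor_at(correct_core, len(e7), half)
    alt1 = _anchor_at(alt_core, len(e7), half)
    alt2 = _anchor_at(alt_core, len(e7) + locus.dup_len, half)

    # SNP anchor: a k-mer inside exon 7 centred on the SNP, shifted (and if
    # necessary shortened to an even length >= 8) at the exon edges.
    k_snp = min(k, len(e7) - len(e7) % 2)
    if k_snp < 8:
        raise ValueError("exon 7 too short for a SNP anchor")
    start = min(max(locus.snp_offset - k_snp // 2, 0), len(e7) - k_snp)
    snp_anchor = (e7[start: locus.snp_offset] + "N"
                  + e7[locus.snp_offset + 1: start + k_snp])
    wild_idx = locus.snp_offset - start

    # Uniqueness: each junction anchor must occur exactly once in its own
    # isoform and never in the other, for either SNP allele and with the
    # minigene flanks attached.
    def variants(core: str, alleles=None) -> list[str]:
        out = []
        for allele in (alleles or locus.snp_alleles):
            s = (core[: locus.snp_offset] + allele
                 + core[locus.snp_offset + 1:])
            out.append(s)
            out.append(locus.minigene_flank5 + s + locus.minigene_flank3)
        return out

    def count_in(anchor: str, seqs: list[str]) -> int:
        return max(s.count(anchor) for s in seqs)

    cor_seqs, alt_seqs = variants(correct_core), variants(alt_core)
    if correct_anchor in (alt1, alt2):
        raise ValueError("ambiguous anchor; increase k")
    for anchor, own, other in ((correct_anchor, cor_seqs, alt_seqs),
                               (alt1, alt_seqs, cor_seqs),
                               (alt2, alt_seqs, cor_seqs)):
        if count_in(anchor, own) != 1 or count_in(anchor, other) != 0:
            raise ValueError("ambiguous anchor; increase k")
    for allele in locus.snp_alleles:
        probe = snp_anchor.replace("N", allele)
        other = [a for a in locus.snp_alleles if a != allele]
        own = variants(correct_core, [allele]) + variants(alt_core, [allele])
        foreign = variants(correct_core, other) + variants(alt_core, other)
        if any(s.count(probe) != 1 for s in own) or \
                any(probe in s for s in foreign):
            raise ValueError("ambiguous SNP anchor; increase k")

    intron_anchor: str | None = None
    if len(locus.intron7_seq) >= locus.dup_len + k:
        cand = locus.intron7_seq[locus.dup_len: locus.dup_len + k]
        genomic = []
        for allele in locus.snp_alleles:
            e7a = e7[: locus.snp_offset] + allele + e7[locus.snp_offset + 1:]
            genomic.append(e7a + locus.intron7_seq)          # wild type
            genomic.append(e7a + dup + locus.intron7_seq)    # duplication
        if all(g.count(cand) == 1 for g in genomic) and \
                not any(cand in s for s in cor_seqs + alt_seqs):
            intron_anchor = cand

    return AnchorSet(correct_anchor=correct_anchor, alt_anchors=(alt1, alt2),
                     snp_anchor=snp_anchor, snp_wild_idx=wild_idx,
                     snp_alleles=tuple(locus.snp_alleles), k=k,
                     max_mismatch=max_mismatch, intron_anchor=intron_anchor)


@dataclass(frozen=True)
class ReadCall:
    splice: str       # correct | alternative | unclassified
    allele: str       # A | G | unclassified
    orientation: str  # fwd | rev


def _window_mismatches(read_arr: np.ndarray, pat_arr: np.ndarray,
                       wild_idx: int | None = None) -> np.ndarray:
    win = sliding_window_view(read_arr, pat_arr.size)
    diff = win != pat_arr
    mm = diff.sum(axis=1)
    if wild_idx is not None:
        mm = mm - diff[:, wild_idx]
    return mm


def _matches(read: str, read_arr: np.ndarray | None, pattern: str,
             max_mismatch: int) -> tuple[bool, np.ndarray | None]:
    """Does ``pattern`` occur within ``max_mismatch`` substitutions?

    Returns the (possibly lazily created) byte array of the read so callers
    can reuse it across anchors.
    """
    if read.find(pattern) >= 0:
        return True, read_arr
    if max_mismatch == 0 or len(read) < len(pattern):
        return False, read_arr
    if read_arr is None:
        read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    pat_arr = np.frombuffer(pattern.encode(), dtype=np.uint8)
    mm = _window_mismatches(read_arr, pat_arr)
    return bool(mm.min() <= max_mismatch), read_arr


def _call_allele(read: str, read_arr: np.ndarray | None, anchors: AnchorSet,
                 ) -> tuple[str, np.ndarray | None]:
    a0, a1 = anchors.snp_alleles
    hit0 = read.find(anchors.snp_anchor.replace("N", a0)) >= 0
    hit1 = read.find(anchors.snp_anchor.replace("N", a1)) >= 0
    if hit0 != hit1:
        return (a0 if hit0 else a1), read_arr
    if hit0 and hit1:
        return UNCLASSIFIED, read_arr      # two SNP sites: ambiguous
    if anchors.max_mismatch == 0 or len(read) < len(anchors.snp_anchor):
        return UNCLASSIFIED, read_arr
    if read_arr is None:
        read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    pat = anchors.snp_anchor.replace("N", "A")  # wildcard column is ignored
    pat_arr = np.frombuffer(pat.encode(), dtype=np.uint8)
    mm = _window_mismatches(read_arr, pat_arr, anchors.snp_wild_idx)
    pos = int(mm.argmin())
    if mm[pos] > anchors.max_mismatch:
        return UNCLASSIFIED, read_arr
    base = read[pos + anchors.snp_wild_idx]
    return (base if base in anchors.snp_alleles else UNCLASSIFIED), read_arr


def classify_read(read: str, anchors: AnchorSet) -> ReadCall:
    """Call splice isoform and SNP allele; both orientations are tried."""
    for orientation in ("fwd", "rev"):
        seq = read if orientation == "fwd" else rm.revcomp(read)
        arr: np.ndarray | None = None
        cor, arr = _matches(seq, arr, anchors.correct_anchor,
                            anchors.max_mismatch)
        alt = False
        for a in anchors.alt_anchors:
            hit, arr = _matches(seq, arr, a, anchors.max_mismatch)
            if hit:
                alt = True
                break
        intronic = False
        if anchors.intron_anchor is not None and (alt or not cor):
            intronic, arr = _matches(seq, arr, anchors.intron_anchor,
                                     anchors.max_mismatch)
        if intronic and not cor:
            splice = rm.NA            # unspliced junction (genomic DNA)
        elif alt and not cor:
            splice = rm.ALTERNATIVE
        elif cor and not alt:
            splice = rm.CORRECT
        else:
            splice = UNCLASSIFIED
        allele, arr = _call_allele(seq, arr, anchors)
        if splice != UNCLASSIFIED or allele != UNCLASSIFIED:
            return ReadCall(splice, allele, orientation)
    return ReadCall(UNCLASSIFIED, UNCLASSIFIED, "fwd")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

SPLICE_LEVELS = (rm.CORRECT, rm.ALTERNATIVE, rm.NA, UNCLASSIFIED)
ALLELE_LEVELS = ("A", "G", UNCLASSIFIED)


@dataclass
class CountTable:
    """Read counts per (splice, allele) cell, unclassified margins included."""

    sample_id: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def n(self, splice: str | None = None, allele: str | None = None) -> int:
        return sum(v for (s, a), v in self.counts.items()
                   if (splice is None or s == splice)
                   and (allele is None or a == allele))

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.sample_id, s, a, self.counts.get((s, a), 0))
                for s in SPLICE_LEVELS for a in ALLELE_LEVELS]
        return pd.DataFrame(rows,
                            columns=["sample_id", "splice", "allele", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        ids = df["sample_id"].unique()
        if len(ids) != 1:
            raise ValueError("expected a single-sample count table")
        counts = {(r.splice, r.allele): int(r.count)
                  for r in df.itertuples() if r.count}
        return cls(sample_id=str(ids[0]), counts=counts)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def aggregate(calls: list[ReadCall], sample_id: str = "sample") -> CountTable:
    """Pure counting of per-read calls into a CountTable."""
    counts: dict[tuple[str, str], int] = {}
    for c in calls:
        key = (c.splice, c.allele)
        counts[key] = counts.get(key, 0) + 1
    return CountTable(sample_id=sample_id, counts=counts)


def classify_reads(reads: list[str], anchors: AnchorSet,
                   sample_id: str = "sample",
                   ) -> tuple[list[ReadCall], CountTable]:
    calls = [classify_read(r, anchors) for r in reads]
    return calls, aggregate(calls, sample_id)
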