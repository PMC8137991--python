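"""Anchor construction and joint splice/allele read calling."""

import numpy as np
import pytest

from oct1splice.classify import (CountTable, UNCLASSIFIED, aggregate,
                                 build_anchors, classify_read, classify_reads,
                                 ReadCall)
from oct1splice.merge import merge_pairs
from oct1splice.refmodel import (GENOMIC, LIVER, LocusModel, Haplotype,
                                 build_isoform, make_toy_locus, revcomp)
from oct1splice.simulate import SampleSpec, simulate_sample


class TestBuildAnchors:
    def test_toy_anchors_are_junction_kmers(self, toy_locus):
        a = build_anchors(toy_locus, k=16)
        assert a.correct_anchor == "GTACGTAC" + "TTGGCCAA"
        assert a.alt_anchors[0] == "GTACGTAC" + "GTAAGTTG"
        assert a.alt_anchors[1] == "GTAAGTTG" + "TTGGCCAA"
        assert a.correct_anchor not in a.alt_anchors

    def test_exon8_repeating_duplication_is_rejected(self):
        # exon 8 begins with the duplicated donor sequence: the correct
        # junction k-mer then equals the alternative one
        locus = LocusModel(exon7_seq="ACGTACGTACGGCCTTAA",
                           intron7_seq="GTAAGTTGCC",
                           exon8_seq="GTAAGTTGCCAATTGGCC",
                           dup_len=8, snp_offset=8)
        with pytest.raises(ValueError, match="ambiguous anchor"):
            build_anchors(locus, k=16)

    def test_anchor_matches_own_isoform_exactly(self, locus, anchors):
        cor = build_isoform(locus, Haplotype(True, "A"), LIVER, "correct").seq
        alt = build_isoform(locus, Haplotype(True, "A"), LIVER,
                            "alternative").seq
        assert cor.count(anchors.correct_anchor) == 1
        assert all(alt.count(a) == 1 for a in anchors.alt_anchors)
        assert all(a not in cor for a in anchors.alt_anchors)
        assert anchors.correct_anchor not in alt

    def test_odd_or_out_of_range_k_rejected(self, locus):
        for k in (7, 15, 42):
            with pytest.raises(ValueError):
                build_anchors(locus, k=k)


class TestClassifyRead:
    def test_error_free_reads_called_correctly(self, locus, anchors):
        for splice in ("correct", "alternative"):
            for allele in ("A", "G"):
                iso = build_isoform(locus, Haplotype(True, allele), LIVER,
                                    splice)
                call = classify_read(iso.seq, anchors)
                assert (call.splice, call.allele) == (splice, allele)

    def test_strand_symmetry(self, locus, anchors):
        iso = build_isoform(locus, Haplotype(True, "A"), LIVER,
                            "alternative")
        fwd = classify_read(iso.seq, anchors)
        rev = classify_read(revcomp(iso.seq), anchors)
        assert (fwd.splice, fwd.allele) == (rev.splice, rev.allele)
        assert rev.orientation == "rev"

    def test_two_errors_in_anchor_unclassified(self, locus, anchors):
        iso = build_isoform(locus, Haplotype(False, "G"), LIVER, "correct")
        j = iso.junction_pos
        seq = list(iso.seq)
        for off in (-2, 1):   # two substitutions inside the junction k-mer
            seq[j + off] = {"A": "C", "C": "A", "G": "T", "T": "G"}[
                seq[j + off]]
        call = classify_read("".join(seq), anchors)
        assert call.splice == UNCLASSIFIED

    def test_single_error_tolerated(self, locus, anchors):
        iso = build_isoform(locus, Haplotype(False, "G"), LIVER, "correct")
        j = iso.junction_pos
        seq = list(iso.seq)
        seq[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[j]]
        call = classify_read("".join(seq), anchors)
        assert call.splice == "correct"

    def test_genomic_reads_called_na(self, locus, anchors):
        for dup in (True, False):
            iso = build_isoform(locus, Haplotype.from_linkage(dup), GENOMIC,
                                "na")
            call = classify_read(iso.seq, anchors)
            assert call.splice == "na"
            assert call.allele == ("A" if dup else "G")

    def test_garbage_read_fully_unclassified(self, anchors):
        call = classify_read("ACGT" * 60, anchors)
        assert call == ReadCall(UNCLASSIFIED, UNCLASSIFIED, "fwd")


class TestAggregate:
    def test_counts_and_margins(self):
        calls = [ReadCall("correct", "A", "fwd"),
                 ReadCall("correct", "G", "fwd"),
                 ReadCall(UNCLASSIFIED, "A", "fwd")]
        ct = aggregate(calls, "s")
        assert ct.total == 3
        assert ct.n(splice="correct") == 2
        assert ct.n(allele="A") == 2
        assert ct.n(splice=UNCLASSIFIED, allele="A") == 1

    def test_empty_input_gives_zero_table(self):
        ct = aggregate([], "s")
        assert ct.total == 0
        assert ct.n(splice="correct") == 0

    def test_roundtrip_tsv(self, tmp_path):
        ct = aggregate([ReadCall("alternative", "A", "fwd")] * 3, "s")
        ct.to_tsv(tmp_path / "c.tsv")
        back = CountTable.from_tsv(tmp_path / "c.tsv")
        assert back.sample_id == "s" and back.counts == ct.counts


class TestEndToEndAccuracy:
    def test_zero_error_classification_is_exact(self, locus, anchors):
        spec = SampleSpec("s", "WT/dup", LIVER, depth=2000,
                          mis_splice_prob=0.4, decay_prob=0.2,
                          error_rate=0.0, seed=31)
        sim = simulate_sample(locus, spec)
        merged = merge_pairs(sim.r1, sim.r2)
        calls, ct = classify_reads([m.seq for m in merged], anchors, "s")
        assert ct.n(splice=UNCLASSIFIED) == 0
        assert ct.n(allele=UNCLASSIFIED) == 0
        for call, row in zip(calls, sim.truth.itertuples()):
            assert call.splice == row.splice
            assert call.allele == row.haplotype[-1]

    def test_truth_aggregation_equals_classifier_aggregation(self, locus,
                                                             anchors):
        spec = SampleSpec("s", "dup/dup", LIVER, depth=1500,
                          mis_splice_prob=0.3, error_rate=0.0, seed=32)
        sim = simulate_sample(locus, spec)
        merged = merge_pairs(sim.r1, sim.r2)
        _, ct = classify_reads([m.seq for m in merged], anchors, "s")
        truth_alt = (sim.truth["splice"] == "alternative").sum()
        assert ct.n(splice="alternative") == truth_alt
        assert ct.n(splice="correct") == spec.depth - truth_alt

    def test_misclassification_rate_below_1e3_with_errors(self, locus,
                                                          anchors):
        spec = SampleSpec("s", "dup/dup", MINIGENE_CTX, depth=30_000,
                          mis_splice_prob=0.38, error_rate=0.003, seed=33)
        sim = simulate_sample(locus, spec)
        merged = merge_pairs(sim.r1, sim.r2, sim.quals1, sim.quals2)
        calls, _ = classify_reads(
            [m.seq for m in merged if m.status == "merged"], anchors, "s")
        truth = sim.truth.loc[[m.status == "merged" for m in merged]]
        wrong = sum(
            1 for call, row in zip(calls, truth.itertuples())
            if call.splice != UNCLASSIFIED and call.splice != row.splice)
        classified = sum(c.splice != UNCLASSIFIED for c in calls)
        assert wrong / classified < 1e-3

    def test_wild_type_sample_has_zero_alternative_calls(self, locus,
                                                         anchors):
        spec = SampleSpec("wt", "WT/WT", LIVER, depth=3000, error_rate=0.0,
                          seed=34)
        sim = simulate_sample(locus, spec)
        merged = merge_pairs(sim.r1, sim.r2)
        _, ct = classify_reads([m.seq for m in merged], anchors, "wt")
        assert ct.n(splice="alternative") == 0
        assert ct.n(splice="correct") == spec.depth


MINIGENE_CTX = "minigene_cDNA"
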