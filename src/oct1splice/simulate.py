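"""Synthetic amplicon-read generator under the splicing + decay model.

Generative model per read pair (cDNA contexts):

1. choose the transcribing haplotype with probabilities proportional to the
   *surviving* transcript pool — the A (duplication) haplotype transcribes
   ``rho`` transcripts per G-haplotype transcript, each duplication-allele
   transcript uses the duplicated donor with probability ``m``
   (mis-splicing), and each alternatively spliced transcript is removed
   before sequencing with probability ``d`` (decay);
2. the fragment is the full amplicon of that isoform (optionally jittered);
3. both 221 bp read ends are observed with iid per-base substitution errors.

Minigene reporter transcripts escape decay surveillance, so ``d = 0`` is the
appropriate minigene setting; genomic DNA amplicons have neither splicing
nor decay. The truth table records each read pair's haplotype, splice status
and injected error count, which downstream modules use as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import refmodel as rm
from .defaults import (CONTEXTS, DEFAULT_ERROR_RATE, GENOTYPES, READ_LEN)

QUAL_CHAR = "?"  # constant Q30; qualities do not drive the analysis

_BASE2IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE2IDX[_b] = _i
_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SampleSpec:
    """Generative parameters of one simulated sample."""

    sample_id: str
    genotype: str                      # WT/WT, WT/dup, dup/dup
    context: str                       # minigene_cDNA, liver_cDNA, genomic_DNA
    depth: int                         # read pairs
    expression_ratio: float = 1.0      # rho: A-haplotype transcripts per G
    mis_splice_prob: float = 0.0       # m, duplication allele only
    decay_prob: float = 0.0            # d, alternative transcripts only
    read_len: int = READ_LEN
    fragment_jitter_sd: float = 0.0    # 0 = fragment is the full amplicon
    error_rate: float = DEFAULT_ERROR_RATE
    linkage_break_prob: float = 0.0    # probability the SNP base is swapped
    seed: int = 0

    def validate(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for nm in ("mis_splice_prob", "decay_prob", "error_rate",
                   "linkage_break_prob"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1]")
        if self.expression_ratio <= 0:
            raise ValueError("expression_ratio must be positive")
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")
        if self.context == rm.GENOMIC and (
                self.mis_splice_prob or self.decay_prob):
            warnings.warn("mis_splice_prob/decay_prob are ignored for "
                          "genomic DNA amplicons", stacklevel=2)
        if self.context == rm.MINIGENE and self.decay_prob:
            warnings.warn("minigene reporter transcripts escape decay; "
                          "nonzero decay_prob is unusual", stacklevel=2)


def surviving_pool_weights(genotype: str, rho: float, m: float, d: float,
                           context: str = rm.LIVER,
                           ) -> dict[tuple[str, str], float]:
    """Expected proportions of the surviving transcript pool per stratum.

    Strata are keyed by ``(met408_allele, splice)``. For a heterozygote with
    rho = 1 the weights are (1-m)/(2-md) for (A, correct), m(1-d)/(2-md) for
    (A, alternative) and 1/(2-md) for (G, correct); they always sum to 1.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    for nm, v in (("rho", rho), ("m", m), ("d", d)):
        if nm == "rho":
            if v <= 0:
                raise ValueError("rho must be positive")
        elif not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm} must be in [0, 1]")

    if context == rm.GENOMIC:
        # No splicing, no decay: allele proportions follow copy number only.
        if genotype == "WT/WT":
            return {("G", rm.NA): 1.0}
        if genotype == "dup/dup":
            return {("A", rm.NA): 1.0}
        return {("A", rm.NA): rho / (1 + rho), ("G", rm.NA): 1 / (1 + rho)}

    if genotype == "WT/WT":
        return {("G", rm.CORRECT): 1.0}
    if genotype == "dup/dup":
        z = 1 - m * d
        if z == 0:
            raise ValueError("m*d = 1: the entire transcript pool decays")
        return {("A", rm.CORRECT): (1 - m) / z,
                ("A", rm.ALTERNATIVE): m * (1 - d) / z}
    # heterozygote: A carries the duplication, G is wild type
    z = rho * (1 - m * d) + 1
    return {("A", rm.CORRECT): rho * (1 - m) / z,
            ("A", rm.ALTERNATIVE): rho * m * (1 - d) / z,
            ("G", rm.CORRECT): 1 / z}


@dataclass
class SimulatedSample:
    spec: SampleSpec
    read_ids: list[str]
    r1: list[str]
    r2: list[str]
    truth: pd.DataFrame     # read_id, haplotype, splice, n_errors
    qual_char: str = QUAL_CHAR

    @property
    def quals1(self) -> list[str]:
        return [self.qual_char * len(s) for s in self.r1]

    @property
    def quals2(self) -> list[str]:
        return [self.qual_char * len(s) for s in self.r2]


def _apply_errors(mat: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Substitute bases iid at ``rate``; returns per-read error counts."""
    if rate <= 0 or mat.size == 0:
        return np.zeros(mat.shape[0], dtype=int)
    mask = rng.random(mat.shape) < rate
    rows, cols = np.nonzero(mask)
    if rows.size:
        idx = _BASE2IDX[mat[rows, cols]]
        shift = rng.integers(1, 4, size=rows.size, dtype=np.uint8)
        mat[rows, cols] = _IDX2BASE[(idx + shift) % 4]
    return mask.sum(axis=1)


def simulate_sample(locus: rm.LocusModel, spec: SampleSpec) -> SimulatedSample:
    """Draw ``spec.depth`` paired-end read pairs from the generative model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.context == rm.GENOMIC:
        weights = surviving_pool_weights(spec.genotype, spec.expression_ratio,
                                         0.0, 0.0, spec.context)
    else:
        weights = surviving_pool_weights(
            spec.genotype, spec.expression_ratio, spec.mis_splice_prob,
            spec.decay_prob, spec.context)
    strata = list(weights)
    probs = np.array([weights[s] for s in strata])
    probs = probs / probs.sum()

    stratum_idx = rng.choice(len(strata), size=spec.depth, p=probs)
    if spec.linkage_break_prob > 0:
        flip = rng.random(spec.depth) < spec.linkage_break_prob
    else:
        flip = np.zeros(spec.depth, dtype=bool)

    # Resolve per-read (allele, splice, dup) and the fragment sequence.
    frag_cache: dict[tuple[str, str, bool], str] = {}
    hap_labels = np.empty(spec.depth, dtype=object)
    splice_labels = np.empty(spec.depth, dtype=object)
    frag_keys = np.empty(spec.depth, dtype=object)
    for i in range(spec.depth):
        allele, splice = strata[stratum_idx[i]]
        dup = (allele == "A") if spec.context == rm.GENOMIC else \
            (splice == rm.ALTERNATIVE or allele == "A")
        if flip[i]:
            allele = "G" if allele == "A" else "A"
        key = (allele, splice, dup)
        if key not in frag_cache:
            iso = rm.build_isoform(
                locus, rm.Haplotype(dup, allele), spec.context,
                splice if spec.context != rm.GENOMIC else rm.NA)
            frag_cache[key] = iso.seq
        hap_labels[i] = f"{'dup' if dup else 'wt'}-{allele}"
        splice_labels[i] = splice
        frag_keys[i] = key

    L = spec.read_len
    for frag in frag_cache.values():
        if L > len(frag):
            raise ValueError("read_len exceeds amplicon length; staggered "
                             "read-through is not modelled")
        if spec.fragment_jitter_sd > 0:
            pass  # jitter is applied per read below

    # Fragments per read (optionally jittered sub-fragments of the amplicon).
    if spec.fragment_jitter_sd > 0:
        frags = []
        for i in range(spec.depth):
            amp = frag_cache[frag_keys[i]]
            flen = int(round(rng.normal(len(amp), spec.fragment_jitter_sd)))
            flen = max(L, min(flen, len(amp)))
            start = rng.integers(0, len(amp) - flen + 1)
            frags.append(amp[start:start + flen])
    else:
        frags = [frag_cache[frag_keys[i]] for i in range(spec.depth)]

    r1_mat = np.empty((spec.depth, L), dtype=np.uint8)
    r2_mat = np.empty((spec.depth, L), dtype=np.uint8)
    for i, frag in enumerate(frags):
        fb = np.frombuffer(frag.encode(), dtype=np.uint8)
        r1_mat[i] = fb[:L]
        # R2 in sequencer orientation: reverse complement of the fragment end
        rc = np.frombuffer(rm.revcomp(frag).encode(), dtype=np.uint8)
        r2_mat[i] = rc[:L]

    nerr1 = _apply_errors(r1_mat, spec.error_rate, rng)
    nerr2 = _apply_errors(r2_mat, spec.error_rate, rng)

    read_ids = [f"{spec.sample_id}:{i:06d}" for i in range(spec.depth)]
    r1 = [row.tobytes().decode() for row in r1_mat]
    r2 = [row.tobytes().decode() for row in r2_mat]
    truth = pd.DataFrame({
        "read_id": read_ids,
        "haplotype": hap_labels,
        "splice": splice_labels,
        "n_errors": nerr1 + nerr2,
    })
    return SimulatedSample(spec=spec, read_ids=read_ids, r1=r1, r2=r2,
                           truth=truth)


def truth_counts(truth: pd.DataFrame) -> pd.Series:
    """Counts by (haplotype, splice) stratum; sums to the sample depth."""
    return truth.groupby(["haplotype", "splice"], sort=True).size()
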