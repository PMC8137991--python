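# Methods

## The biological problem

OCT1 (gene *SLC22A1*) is the dominant hepatic uptake transporter for weakly
basic drugs. The common insertion/deletion variant rs35854239 duplicates the
first eight bases of intron 7 — including the canonical GT splice donor —
immediately after exon 7, so duplication-allele pre-mRNA carries two usable
donor sites eight bases apart. When the downstream (duplicated) donor is
used, the mature transcript retains the eight extra bases, the reading frame
shifts, and a premature termination codon appears shortly afterwards; the
truncated protein lacks the C-terminal transmembrane helices and is
non-functional. Premature-termination transcripts are also substrates of
nonsense-mediated decay (NMD), so the alternative transcript is largely
removed before it can be observed in liver RNA.

The package quantifies this chain of events from targeted amplicon deep
sequencing: how often the duplicated donor is used (mis-splicing), how much
of the alternative transcript survives decay, and what that implies for
allele-specific expression and downstream genotype–phenotype contrasts.

## Generative model

Each simulated read pair from a cDNA library is drawn as follows
(`simulate.SampleSpec`):

1. **Haplotype.** The duplication travels with the Met408 (rs628031) A
   allele; the wild-type haplotype carries G. A heterozygote transcribes the
   A haplotype at rate ρ relative to G (default ρ = 1, equal allelic
   transcription). An optional `linkage_break_prob` (default 0) swaps the
   marker allele per read to represent the ~5% of haplotypes where the
   r² ≈ 0.95 linkage is broken; the default keeps complete linkage because
   the imbalance analysis itself assumes the linked haplotype.
2. **Splicing.** A duplication-haplotype transcript uses the duplicated
   donor with probability *m*; wild-type transcripts have a single donor
   (*m* ≡ 0).
3. **Decay.** An alternatively spliced transcript survives to the sequenced
   pool with probability 1 − *d*. Decay is modelled as pre-sequencing
   thinning of transcripts, not read-level filtering, matching the
   interpretation that the transcripts are degraded in the cell. Reporter
   minigene transcripts (heterologous flanking exons) escape NMD, so *d* = 0
   is the appropriate minigene setting; genomic DNA amplicons ignore *m* and
   *d* entirely.
4. **Sequencing.** The fragment is the full isoform amplicon (amplicon
   sequencing; optional Gaussian length jitter exists but defaults to off).
   Both ends are read at 221 bp with iid per-base substitution errors at
   rate *e* (default 0.003). Qualities are constant Q30 — errors, not
   qualities, drive the analysis. Indel errors, PCR duplicates and chimeras
   are not modelled (documented limitation).

The surviving-pool stratum weights for a heterozygote at ρ = 1 are
(1−m)/(2−md) for (A, correct), m(1−d)/(2−md) for (A, alternative) and
1/(2−md) for (G, correct); for a duplication homozygote the denominator is
1−md. These closed forms are cross-checked in the tests against a direct
Monte-Carlo enumeration of transcript fates.

## Synthetic locus

The amplicon sequences of the real locus are not distributed with the
package, so a deterministic synthetic locus stands in (`make_default_locus`,
fixed internal seed): a 180 bp exon 7 with the marker SNP at offset 100, an
intron 7 beginning `GTAAGT`, a 120 bp exon 8, and 40 bp reporter-exon
flanks for the minigene context. The locus reproduces the *architecture*
that the analysis depends on — tandem duplication of the intron head, a
readable SNP within the merged read, junction k-mers unique at k = 16 —
while the base composition is random. A real locus can be supplied as a
FASTA (records `exon7`, `intron7`, `exon8`, optional flanks) plus a JSON
sidecar (`dup_len`, `snp_offset`, `snp_alleles`). Consequently, passing
tests demonstrate correctness of the measurement and inversion machinery
under the model's assumptions, not properties of any particular genome
build; sequence-specific artefacts of real libraries (context-dependent
error rates, coverage bias, index hopping) are out of scope.

## Read merging

Amplicons (240–390 bp here) are shorter than twice the 221 bp read length,
so the pairs overlap near-fully. `merge.merge_pair` scans every overlap of
at least `min_overlap` (default 10) between R1 and the reverse complement of
R2, scores each as matches − mismatches, keeps the maximal score with ties
broken toward the longer overlap, and accepts if the overlap mismatch
fraction is ≤ `max_mismatch_frac` (default 0.1). Consensus bases take the
higher-quality read, ties toward R1. This is a deliberate simplification of
PEAR-style merging: the statistical significance test is omitted because
near-full overlaps make it uninformative at these geometries. Staggered
overlaps (fragment shorter than one read) are not supported.

## Classification

The only difference between the isoforms is a fixed 8 bp insertion at a
known junction, so presence/absence k-mer anchors replace alignment
(`classify.build_anchors`, k = 16, max 1 mismatch, both defaults
CLI-exposed):

* correct isoform: the k-mer spanning exon7|exon8;
* alternative isoform: the k-mers spanning exon7|duplication and
  duplication|exon8;
* marker allele: a k-mer inside exon 7 centred on the SNP with the SNP base
  wildcarded (shifted at exon edges);
* genomic/unspliced material: a k-mer strictly inside intron 7 beyond the
  duplicated head. This anchor is needed because the duplication is a
  tandem copy of the intron head: a genomic exon7|intron junction is
  sequence-identical to the alternative transcript's exon7|duplication
  junction, and without the intron anchor every DNA read would be
  mis-called as alternative. Reads carrying the intron anchor (and not the
  correct-junction anchor) are called splice = `na`.

A read is `alternative` iff an alternative anchor matches within the
mismatch budget and the correct anchor does not, `correct` in the converse
case, and `unclassified` whenever anchors conflict or none match — ambiguity
is always surfaced, never imputed, and unclassified fractions appear in the
QC output and are excluded from every denominator. Both read orientations
are tried. Anchor construction verifies that every anchor occurs exactly
once in its own isoform and never in the other (for both SNP alleles, with
and without minigene flanks) and refuses ambiguous sets with instructions to
increase k — e.g. when exon 8 happens to begin with the duplicated
sequence.

With k = 16 and one tolerated mismatch at e = 0.003, a splice call requires
two errors inside a 16-mer (per-read probability ≈ 10⁻³ of becoming
unclassified) and a false cross-isoform hit requires ≥ 5 specific errors, so
the misclassification rate among classified reads is far below 10⁻³
(verified against the simulator's truth tables). Residual known leakage:
a genomic read whose intron anchor is destroyed by errors (~0.1% of DNA
reads) falls back to an `alternative` call; DNA libraries never contribute
to splice-fraction denominators, so this does not affect the estimands.

## Estimands and inversion

* **Splice fraction** — correct/(correct+alternative) with a Wilson score
  95% CI (z = 1.959964). Wilson rather than Wald because liver alternative
  fractions near 0.3% make Wald intervals degenerate; empirical coverage is
  verified to sit in [93%, 97%] at n = 500.
* **Allele fraction** — A/(A+G), over all allele-classified reads or the
  correctly spliced stratum only.
* **AEI test** — per-donor paired differences of DNA and RNA A-allele
  fractions, two-sided paired t-test (exact t CDF). A zero-variance
  difference vector is reported with an explicit flag instead of NaN.
* **Inversion** — from the heterozygote RNA allele fraction:
  md = (1−2f)/(1−f); adding the surviving alternative fraction separates
  m = md + alt·(2−md) and d = md/m. Estimates outside [0, 1] are clamped
  with flags; f ≥ 0.5 yields md = 0 with a "no detectable imbalance" flag.
  The forward map and the inversion are verified to be mutual inverses to
  10⁻⁹ over the open unit square, and f is strictly decreasing in md.
* **Ratio estimator** — the correct-read A/G ratio estimates m = 1 − r
  independently of the alternative fraction. The published observations
  over-determine the two parameters: f = 0.42 with alt = 0.36% gives
  (m, d) = (0.282, 0.978), while f = 0.42 with r = 71.3% gives
  (0.287, 0.961). The package reports both estimators and does not
  reconcile them; note that under (0.287, 0.961) the implied heterozygote
  alternative fraction is 0.65%, not 0.36% — the three published fractions
  cannot hold simultaneously under this model, and the corresponding
  acceptance check documents the discrepancy rather than hiding it.
* **Pyrosequencing calibration** — abstracted as an ordinary least-squares
  line fitted to a known-fraction calibration series, inverted with
  clamping to [0, 1].

## Protein consequence

`frameshift_consequence` translates a CDS with an arbitrary insertion and
reports: the count of leading codons identical to wild type, the number of
novel residues before the first stop in the mutant frame, the truncated
length, and the 1-based stop position. The literature describes the studied
event with two off-by-one conventions ("altered after codon 425, stop after
seven residues" vs naming residue 431); all fields are reported so either
convention can be read off, and none is hard-coded. In-frame insertions
without stops take a "no premature stop" path whose translated length is
wild type + len(ins)/3. The analysis driver uses a synthetic 554-codon CDS
(labelled synthetic — the real CDS is not shipped) engineered to reproduce
the event geometry.

## Cohort statistics

Homozygote groups are contrasted with a two-sided Mann–Whitney U test
(α = 0.05): exact enumeration when min(n) ≤ 8 without ties, otherwise the
normal approximation with tie and continuity corrections (scipy backend; an
independent enumeration oracle is kept in the tests). Effect sizes are
percent reductions of group medians, reported unrounded and rounded —
printed group medians 0.014/0.026 give 46.15% unrounded, which rounds to
46% although 47% circulates from unrounded medians; both are checkable from
the unrounded output. Because no method is stated for the "share of
variability explained", the package's own choice is the R² of an ordinary
least-squares regression of log phenotype on duplication-allele dosage
(0/1/2) with a seeded permutation p-value (1,000 permutations); this choice
is recorded in the output metadata. Synthetic cohorts are log-normal with a
log-additive per-allele median shift, genotype counts from Hardy–Weinberg at
duplication allele frequency 0.406, and cohort sizes matching the published
groups (73 liver donors; 40 trial participants where group sizes are not
printed — a package choice).

## Determinism and problem sizes

Every random stage takes a seed; pipeline runs derive per-sample seeds from
the global seed and sample index through `numpy.random.SeedSequence`, and
identical configs produce byte-identical outputs (hash-verified in tests).
The analysis drivers run at 12,000–20,000 read pairs per library, chosen so
binomial uncertainty on the reported fractions stays below a tenth of a
percentage point while a full run of all drivers completes in about a
minute; the acceptance script re-runs the headline estimates at the full
study depths (59,135 and 74,326 merged pairs).

## Known limitations

* Substitution errors only; no indels, PCR duplicates, chimeras or
  quality-dependent error profiles.
* Single-junction isoform structures only; no general multi-exon support,
  no BAM/SAM emission, no general variant calling.
* The inversion assumes equal allelic transcription and complete linkage;
  deviations are available as simulation scenarios, not estimator inputs.
* Equivalence to local-alignment read counting is expected at the level of
  fraction estimates, not per-read decisions.
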