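"""Named study-default parameters, in one place.

These are the conditions under which the reproduction analyses run: sequencing
geometry of the targeted MiSeq assay, the depths reported for the minigene and
liver experiments, and the point estimates of the splicing/decay model that the
quantification module inverts from the published read fractions.
"""

# Sequencing geometry -------------------------------------------------------
READ_LEN = 221            # paired-end read length of the targeted assay, bp
DEFAULT_ERROR_RATE = 3e-3  # per-base substitution probability

# Depths (merged read pairs per sample) -------------------------------------
MINIGENE_DEPTH = 59_135   # mean depth of the minigene RNA amplicon libraries
LIVER_DEPTH = 74_326      # mean depth of the liver RNA/DNA amplicon libraries

# Classifier ---------------------------------------------------------------
DEFAULT_ANCHOR_K = 16
DEFAULT_MAX_MISMATCH = 1

# Merger -------------------------------------------------------------------
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_FRAC = 0.1

# Splicing / decay model point estimates ------------------------------------
# Minigene context: duplication-allele transcripts use the duplicated donor
# with probability ~0.38 (deep-sequencing estimate; reporter transcripts
# escape nonsense-mediated decay, so d = 0 there).
MINIGENE_MIS_SPLICE = 0.38

# Liver context: mis-splicing probability m inferred from the correct-read
# A/G ratio (r = 1 - m = 0.713) and decay probability d = md/m with the
# md product inferred from the RNA A-allele fraction of 0.42.
LIVER_MIS_SPLICE = 0.287
LIVER_DECAY = 0.961

# Observed surviving alternative-read fractions by genotype (liver RNA).
HET_ALT_FRACTION = 0.0036   # heterozygous duplication carriers, group mean
HOM_ALT_FRACTION = 0.0058   # homozygous duplication carriers, group mean

# Duplication ---------------------------------------------------------------
DUP_LEN = 8

GENOTYPES = ("WT/WT", "WT/dup", "dup/dup")
CONTEXTS = ("minigene_cDNA", "liver_cDNA", "genomic_DNA")
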