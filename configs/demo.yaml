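# Demo pipeline config: one minigene sample plus a heterozygous liver
# DNA/RNA pair at desk-scale depth. Run with:
#   oct1splice run-all --config configs/demo.yaml
schema_version: 1
seed: 42
out_dir: results/demo_run
samples:
  - sample_id: minigene_dup
    genotype: dup/dup
    context: minigene_cDNA
    depth: 5000
    mis_splice_prob: 0.38
  - sample_id: liver_het_rna
    genotype: WT/dup
    context: liver_cDNA
    depth: 5000
    mis_splice_prob: 0.287
    decay_prob: 0.961
  - sample_id: liver_het_dna
    genotype: WT/dup
    context: genomic_DNA
    depth: 5000
aei_pairs:
  - dna: liver_het_dna
    rna: liver_het_rna
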