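# bundled end-to-end run: problem sizes scaled for a single-CPU run
seed: 0
sim:
  n_genes: 600
  chrom_length: 150000
  n_dmrs: 40
  n_atac_genes: 50
  ari_up_enrichment: 2.0
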