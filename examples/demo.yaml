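# Desk-scale demo configuration for `dsbdart run`.
# A 2 x 300 kb genome, 50 genes, 12 cut + 12 uncut sites plus one deliberately
# gene-free site (removed by the sense/antisense exclusion rule), 10 bp bins.
bin_size: 10
pathway_k: 4
simulate:
  chromosome_length: 300000
  n_genes: 50
  n_cut_sites: 12
  n_uncut_sites: 12
  n_gene_free_sites: 1
  replicates: 2
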