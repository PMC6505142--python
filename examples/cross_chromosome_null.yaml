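# Null configuration: the distal marker is independent of the QTL-proximal
# pair, so the population interaction coefficient is zero and the rejection
# rate should sit at the significance level.
#
# Run with:
#   phantomld experiment run examples/cross_chromosome_null.yaml --out results/null.tsv
experiment: cross_chromosome_null
master_seed: 1
params:
  n_grid: [10000, 250000]
  phi: 0.01                # fraction of phenotypic variance from the QTL
  qtl_marker_D: 0.08       # haploid LD between the QTL and the proximal marker
  allele_freqs: [0.5, 0.5, 0.4]
  alpha: 0.05
  replicates: 2000
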