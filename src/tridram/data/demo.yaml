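# Bundled demo configuration: one small chromosome, planted TAD blocks,
# anchored read pairs with a positive co-accessibility odds ratio, and
# lambda/pUC19 spike-in controls. Runs end-to-end in a couple of minutes.

simulate:
  genome_length: 500000
  n_chroms: 1
  restriction_motif: GATC
  restriction_spacing: 400
  gpc_spacing: 15
  cpg_spacing: 60
  tad_boundaries: [100000, 200000, 300000, 400000]
  tad_boost: 3.0
  decay_exponent: 1.0
  min_dist: 1000
  n_pairs: 30000
  n_anchored_pairs: 4000
  anchor_features:
    - [chr1, 120000, "+", ctcf_a1]
    - [chr1, 150000, "-", ctcf_b1]
    - [chr1, 230000, "+", ctcf_a2]
    - [chr1, 270000, "-", ctcf_b2]
    - [chr1, 320000, "+", ctcf_a3]
    - [chr1, 380000, "-", ctcf_b3]
  marginal_open_prob: [0.3, 0.3]
  odds_ratio: 3.0
  background_open_prob: 0.15
  p_meth_given_open: 0.8
  p_meth_given_closed: 0.05
  cpg_meth_baseline: 0.75
  conversion_failure: 0.01
  read_len: 100

spikein:
  n_calls: 20000
  epsilon: 0.02

junction_reads:
  n_reads: 500
  read_len: 150

tracks:
  min_cov: 5

singlemol:
  window: 100
  min_sep: 1000
  k: 4
  threshold: 0.5
  min_calls: 1

hic:
  bin_size: 1000
  insulation_flank: 50000
  boundary_quantile: 0.9
  boundary_local_span: 2000
  decay_bins: 30
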