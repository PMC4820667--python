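# Demo pipeline configuration: full 265-sample cohort, thinned panels.
# Run with: sepstrat pipeline run --config examples/demo.yaml --out demo/
seed: 1
simulate:
  n_samples: 265
  n_probes: 3142
  n_snps: 1200
  n_de_probes: 370
  n_cis_eqtl: 80
  n_trans_eqtl: 10
  n_group_specific: 10
discover:
  variance_fraction: 0.10
  k_min: 2
  k_max: 4
de:
  fc_threshold: 1.5
  fdr_threshold: 0.05
  adjust_cell_proportion: false
classify:
  screen_top_k: 200
  loocv: true
geneset:
  n_rotations: 9999
  signature_size: 150
eqtl:
  n_pcs_main: 30
  n_pcs_group: 25
  n_random_pairs: 20000
epimarks: {}
survive:
  horizons: [14, 28]
stages: [simulate, discover, de, classify, geneset, eqtl, epimarks, survive]
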