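{
  "n_genes": 6,
  "nodes_per_gene": [6, 7],
  "n_cell_types": 4,
  "pools_per_type": [4, 4],
  "pool_size": 5,
  "noise_sd": 0.05,
  "na_rate": 0.05,
  "low_read_frac": 0.05,
  "planted_markers": [[0, 0.4, "inclusion"]],
  "planted_mxe": [[1, 0.9, 0.1]],
  "planted_blocks": [[2, 3, 0.4, "above"]]
}
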