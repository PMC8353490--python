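# Example end-to-end configuration for `clonedyn run --config <file>`.
stages: [simulate, extract, normalize, markov, dynamics, history]
out_dir: clonedyn_out
seeds:
  simulate: 1
  sort: 2
  fastq: 3
  barcodes: 4
simulate:
  n_lineages: 200
  initial_cells_per_lineage: 500
  mode: mixed
  mixed_fraction: 0.3
  coordination_prob: 0.5
  sort_fraction: 1.0
amplicon:
  per_base_error_rate: 0.001
  reads_per_cell: 0.5
normalize:
  scheme: default
alpha: 0.05
history_depth: 2
correction: bh
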