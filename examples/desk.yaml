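# Desk-scale study: three synthetic datasets, 10 stratified 20% subsamples,
# 12-configuration neighbors x resolution Leiden grid.
# Omitting `simulation:` uses the three bundled desk datasets (5/8/10
# populations); the sweep block below restricts the full 192-configuration
# grid to its neighbors x resolution face.
n_replicates: 10
subsample_fraction: 0.2
preprocess:
  min_cells: 3
  target_sum: 10000
  n_hvg: 2000
sweep:
  pcs: [10]
  neighbors: [10, 20, 30]
  resolutions: [0.5, 0.8, 1.0, 2.0]
  methods: [umap]
  metrics: [euclidean]
analysis:
  effects: true
  predict: true
  cross_dataset: true
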