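# scsweep

Graph-based clustering of single-cell RNA-seq data depends on parameter
choices — how many principal components to keep, how many nearest
neighbors to connect, which neighbor-graph method (Gaussian kernel or UMAP
fuzzy connectivities) and distance metric to use, and at which resolution
to run community detection.  **scsweep** is a pipeline for studying that
dependence quantitatively on *labeled* data, and for asking whether
clustering accuracy can be predicted *without* labels from intrinsic
cluster-validity indices.

It is aimed at computational biologists who tune Leiden-style clustering
pipelines and want a principled, reproducible way to (1) measure how each
parameter moves accuracy and (2) pick label-free proxies for accuracy.

## What it computes

Given a cell-by-gene count matrix with ground-truth cell-type labels
(synthetic, from the built-in simulator, or loaded from 10x-style Matrix
Market / CSV files), the pipeline:

1. draws R stratified subsamples (default 20% of cells, preserving
   cell-type proportions);
2. preprocesses each subsample (gene filter, library-size normalization,
   log1p, highly-variable-gene selection, PCA);
3. clusters every subsample under a full-factorial parameter grid —
   PC ∈ {10, 20, 30, 50} × NN ∈ {10, 20, 30} × resolution
   ∈ {0.5, 0.8, 1, 2} × method ∈ {gauss, umap} × metric
   ∈ {cosine, euclidean}, 192 configurations — with Leiden community
   detection;
4. scores each clustering against the truth (majority-vote accuracy, ARI,
   NMI) and computes **15 intrinsic validity indices** on the same PCA
   embedding: TSS, within-cluster dispersion (WC = Σₖ Σ_{i∈Cₖ}‖xᵢ−cₖ‖²),
   Ball–Hall, Banfield–Raftery (Σₖ nₖ ln(Tₖ/nₖ)), PBM, Wemmert–Gancarski,
   Xie–Beni, Ray–Turi, McClain–Rao, C-index, Dunn, Silhouette,
   Point-Biserial, and the SD scattering/separation components;
5. fits a Huber-robust linear model of accuracy on the parameters
   (treatment coding, first-order interactions, subsample block effect)
   with bias/RMSE/R² diagnostics, Kruskal–Wallis + Dunn dataset
   comparisons, and best/worst-configuration extraction;
6. fits an elastic net (l1_ratio = 0.5, α by 5-fold CV) predicting
   accuracy from the z-scored indices, validated intra-dataset
   (leave-one-replicate-out) and cross-dataset, with sign-consistent
   feature ranking, Spearman correlation/dendrogram analysis of the
   indices, and a linearity-deviation score per candidate proxy.

## Worked example

```python
from scsweep import (PopulationSpec, generate_dataset, stratified_subsample,
                     SweepConfig, run_sweep)

spec = PopulationSpec(n_cells_per_cluster=(200, 150, 100, 80, 70), seed=3)
data = generate_dataset(spec, dataset_id="demo")
subsamples = stratified_subsample(data.labels, fraction=0.2, n_replicates=2, seed=11)
grid = SweepConfig(pcs=(10,), neighbors=(10, 30), resolutions=(0.5, 2.0),
                   methods=("umap",), metrics=("euclidean",), seed=5)
records = run_sweep(data, subsamples, grid)
print(records[["replicate", "nn", "res", "n_clusters", "accuracy", "ari",
               "wc_dispersion", "banfield_raftery"]].round(3).to_string(index=False))
```

```
 replicate  nn  res  n_clusters  accuracy   ari  wc_dispersion  banfield_raftery
         0  10  0.5           3     0.725 0.654      23841.283           634.041
         0  10  2.0          11     0.933 0.466      16472.448           588.459
         0  30  0.5           3     0.725 0.654      23841.283           634.041
         0  30  2.0          10     0.900 0.481      16402.276           587.776
         1  10  0.5           3     0.725 0.637      24357.377           637.315
         1  10  2.0          13     0.883 0.322      15270.407           577.786
         1  30  0.5           3     0.700 0.546      24828.247           638.927
         1  30  2.0          11     0.875 0.404      16297.058           585.808
```

The dataset has 5 true populations.  At resolution 0.5 the Leiden
partition merges them into 3 communities and accuracy sits at ~0.72; at
resolution 2 the graph is over-partitioned (10–13 communities) but
majority-vote accuracy rises to ~0.9.  The two within-scatter indices
move opposite to accuracy — lower dispersion, better clustering — which
is exactly the proxy relationship the downstream elastic-net analysis
quantifies.

## Command line

The same stages are available as a CLI:

```bash
scsweep simulate --config sim.yaml --out data/ --seed 1
scsweep sweep    --data data/alpha --config sweep.yaml --out records.csv --seed 1
scsweep metrics  --embedding emb.csv --labels labels.tsv --out metrics.json
scsweep effects  --records records.csv --out effects/
scsweep predict  --records records.csv --out predictor/
scsweep run-all  --config run.yaml --out run/ --seed 1
```

`run-all` writes `sweep_records.csv` (one row per dataset × replicate ×
configuration, with scores and all 15 indices), the effect-model outputs
(`effects_coefficients.csv`, `effects_diagnostics.json`,
`extreme_configs.json`, `dataset_comparison.json`), the predictor outputs
(`predictor_coefficients.csv`, `validation_report.json`,
`feature_ranking.csv`, `metric_correlations.csv`,
`linearity_deviation.csv`) and a `manifest.json` with the config hash and
per-stage timings.  Re-running the same config and seed reproduces every
CSV/JSON byte-identically.

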