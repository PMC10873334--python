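# convimpute

Selective recovery of dropout-affected entries in single-cell RNA-seq
count matrices.

Droplet scRNA-seq measurements miss a large share of truly expressed
transcripts ("dropout"), leaving expression matrices dominated by zeros
that bias clustering and differential-expression analysis downstream.
`convimpute` addresses this with a two-part design aimed at imputing
*only* what is actually missing:

1. **Dropout-probability estimation.** After CPM normalisation and a
   log1p transform, cells are grouped (t-SNE embedding, density-peak
   cluster-number estimation, k-means). Within each cluster the log
   expression of each gene is modelled as a gamma-normal mixture

       f(x) = η·Γ(x; α, β) + (1 − η)·N(x; μ, σ²),

   fitted by EM; the posterior weight of the gamma (dropout) component at
   an observed value is its dropout probability DP. Entries with
   DP > T (default 0.5) are called missing.

2. **Convolutional recovery.** Genes with any missing entry become
   targets, partitioned into blocks of 512. Each block, per cluster, gets
   a small 1D CNN (conv16/k3 → pool → batch-norm, twice; dropout 0.3;
   dense 1024; linear output) that predicts the block's 512 targets from
   the 2560 most-correlated low-dropout input genes, trained cell-by-cell
   with a masked MSE so padded slots and missing entries never contribute
   to the loss. Predictions are written back only into entries with
   DP > T — everything else stays bit-identical.

The package also ships a gamma-Poisson simulator with cell groups,
planted differential expression and expression-dependent logistic dropout
(ground truth retained), and an evaluation harness (masking accuracy,
Gini/RNA-FISH concordance with housekeeping rescaling, entropy/purity/ARI
cluster metrics, DEG-recovery AUC and NED). It is aimed at
computational-biology practitioners who need a dropout-aware imputation
step, and at method developers who need a controlled benchmark.

## Worked example

Simulate a grouped dataset with dropout, impute it, and evaluate cluster
quality against the known groups (`--de-fac-loc 1.0` strengthens the
planted differential expression so the five groups are visibly
separable; the default 0.1 produces deliberately subtle groups):

```sh
convimpute simulate --genes 2000 --cells 500 --de-fac-loc 1.0 \
    --seed 7 --outdir sim/
convimpute impute --input sim/observed_counts.csv \
    --output sim/imputed.csv --labels-out sim/pred_labels.tsv \
    --epochs 30 --seed 1
convimpute evaluate cluster-metrics --input sim/observed_counts.csv \
    --labels sim/pred_labels.tsv --truth sim/group_labels.tsv
```

The impute step (a few minutes on one CPU) prints a short JSON summary:

```
{"n_imputed": 481261, "k": 6, "output": "sim/imputed.csv"}
```

meaning the pipeline formed 6 cell clusters and replaced 481,261 entries
whose dropout probability exceeded 0.5 (all other entries are unchanged
bit for bit). The evaluate step prints

```
{"entropy": 0.170, "purity": 0.912, "ari": 0.595}
```

— entropy near 0 and purity near 1 say each recovered cluster is
dominated by one true group; the ARI of 0.6 reflects the pipeline
splitting five overlapping groups into six clusters. Exact numbers vary
with seeds and library versions.

The same stages are available as a library:

```python
from convimpute import SimulationParams, simulate, impute_in_memory

d = simulate(SimulationParams(n_genes=500, n_cells=400, seed=7))
imputed, labels, dp, report = impute_in_memory(d.to_matrix())
```

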