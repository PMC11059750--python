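# chlnmf

Robust non-negative matrix factorization for single-cell expression data,
with hypergraph-Laplacian regularization, plus the downstream clustering,
scoring and marker-gene ranking that turn the learned factors into biology.

## The problem

Clustering cells from scRNA-seq expression matrices is hard because the data
are high-dimensional, noisy, and contaminated: some cells are dominated by
technical noise and behave as outliers. Classical NMF factorizes the
genes × cells matrix **X** ≈ **UV** by minimizing the squared Frobenius
error, which lets a single corrupted cell dominate the fit, and it ignores
the neighborhood structure among cells.

This package addresses both weaknesses at once. It minimizes, over
**U**, **V** ≥ 0,

```
F(U, V) = Σ_j ln(1 + ‖x_j − U v_j‖² / c²)  +  α · Tr(V L Vᵀ)
```

where the sum runs over cell columns, `c` is the Cauchy scale and **L** is
the unnormalized hypergraph Laplacian over cells, `L = D_v − H W D_e⁻¹ Hᵀ`.
The logarithmic (Cauchy) loss grows slowly in the residual, so an outlying
cell contributes bounded influence; the hypergraph term pulls the
coefficient columns of cells that share hyperedges (a cell plus its *p*
most-affine neighbors) toward each other, preserving higher-order
neighborhood structure.

Optimization is half-quadratic: one auxiliary weight per cell,
`ω_j = 2 / (c² + ‖x_j − U v_j‖²)`, turns the robust loss into a weighted
quadratic, and both factors follow multiplicative updates that preserve
non-negativity and never increase the objective. Cells with small final
`ω_j` are exactly the ones the model judged outlying.

Downstream, cells are clustered by K-means on the columns of **V**,
partitions are scored with NMI and the adjusted Rand index, and marker
genes are ranked by Laplacian Score on a k-nearest-neighbor graph built
from Pearson similarity between coefficient columns (low score = gene
respects the cluster structure = likely marker).

## Worked example

```python
import numpy as np
import chlnmf as ch

# 200 genes x 120 cells, 3 populations, 10% of cells replaced by
# heavy-tailed noise (outliers keep their original truth label)
spec = ch.SyntheticSpec(seed=0, outlier_fraction=0.1)
X, truth, planted = ch.generate(spec)

G = ch.build_hypergraph(X, p=5)                    # cell hypergraph
res = ch.fit(X, G, ch.FactorizationConfig(rank=3, seed=0))

labels = ch.kmeans_cluster(res.V, n_clusters=3, seed=0)
print(f"ARI = {ch.ari(truth, labels):.3f}   NMI = {ch.nmi(truth, labels):.3f}")

base = ch.nmf(X, rank=3, seed=0)                   # Frobenius baseline
print(f"plain-NMF ARI = {ch.ari(truth, ch.kmeans_cluster(base.V, 3, seed=0)):.3f}")

out_cells = res.omega < np.median(res.omega) / 10  # tiny HQ weight = outlier
print(f"cells flagged by small omega: {int(out_cells.sum())}")

S = ch.pearson_similarity(res.V)
scores = ch.laplacian_score(X, S, knn=5)
print(ch.top_markers(scores, X.gene_ids, top_n=10).top)
```

Output:

```
ARI = 0.806   NMI = 0.786
plain-NMF ARI = -0.001
cells flagged by small omega: 12
['gene_25', 'gene_24', 'gene_7', 'gene_21', 'gene_9', 'gene_12',
 'gene_161', 'gene_14', 'gene_113', 'gene_13']
```

The robust model recovers the three populations (ARI 0.81) where the
Frobenius baseline is at chance level; the 12 contaminated cells are
exactly the ones with collapsed `ω`; 8 of the 10 top-ranked genes are
planted markers (the planted ids are `gene_0` … `gene_29`).

The same workflow is available from the shell via the `chlnmf` console
script (`simulate`, `hypergraph`, `factorize`, `cluster`, `evaluate`,
`markers`, and `run` for the whole pipeline from a YAML config).

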