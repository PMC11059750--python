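# Methods

## Model

The package factorizes a non-negative genes × cells expression matrix
**X** (m × n) as **X** ≈ **UV** with **U** (m × k) a basis of gene
programs and **V** (k × n) per-cell coefficients, by minimizing

F(U, V) = Σ_j ln(1 + ‖x_j − U v_j‖² / c²) + α · Tr(V L Vᵀ),  U, V ≥ 0,

where the sum runs over the n cell columns. Two modelling choices define
the method:

**Robust reconstruction loss.** The Cauchy loss ln(1 + t/c²) is applied to
each cell's squared residual. Its derivative in t is 1/(c² + t), so a
cell's influence on the gradient decays as its residual grows: a cell the
model cannot explain (an outlier) is progressively ignored rather than
allowed to dominate, which is the failure mode of the squared Frobenius
loss. The scale `c` sets where down-weighting begins; residuals well below
`c` are treated quadratically, residuals well above contribute only
logarithmically.

**Hypergraph regularizer.** Pairwise graphs encode only binary relations;
a hypergraph joins each cell to its whole local neighborhood in one
hyperedge, so the penalty acts on groups of mutually similar cells.
Construction: affinities A_ij = exp(−‖x_i − x_j‖²/σ²) with σ defaulting to
the mean pairwise Euclidean distance; one hyperedge per cell containing the
cell and its p most-affine neighbors (ties broken by ascending cell index);
edge weight w(e_i) = Σ_{j ∈ e_i} A_ij including the seed's A_ii = 1. With
incidence **H** (n × n), W = diag(w), vertex degrees d(v) = Σ_e w(e)H(v,e)
and edge degrees δ(e) = Σ_v H(v,e), the similarity is S = H W D_e⁻¹ Hᵀ and
the unnormalized Laplacian L = D_v − S, which is symmetric positive
semi-definite with zero row sums. Tr(V L Vᵀ) penalizes coefficient
differences among cells sharing hyperedges. The hyperedge construction rule
(seed + p nearest neighbors) is the standard one in hypergraph-regularized
factorization; the normalized (Zhou-style) Laplacian and learned edge
weights are out of scope.

## Optimization

The objective is non-convex and non-quadratic. Half-quadratic duality
replaces each ln term by min over an auxiliary weight:
ln(1 + t/c²) = min_ω { ½ω t + θ(ω) }, attained at ω* = 2/(c² + t). Each
iteration therefore:

1. sets ω_j = 2/(c² + ‖x_j − U v_j‖²) (Λ = diag(ω));
2. takes one multiplicative step on the basis,
   U ← U ∘ (X Λ Vᵀ) ⊘ (U V Λ Vᵀ + ε);
3. takes one multiplicative step on the coefficients,
   V ← V ∘ (Uᵀ X Λ + 2α V S) ⊘ (Uᵀ U V Λ + 2α V D_v + ε).

The coefficient 2α on the graph terms is deliberate: the gradient of
α·Tr(V L Vᵀ) is 2α V L while the half-quadratic data term ½ω_j‖·‖² — the
convention under which ω* = 2/(c² + t) is the exact minimizer — carries its
factor of two inside ω. Only this pairing makes step 3 a true
majorize–minimize step for F; pairing the same ω with α instead silently
optimizes F with half the stated regularization and can increase F from one
iteration to the next (observed empirically at α = 10 before this pairing
was fixed). With ω frozen at ones and α = 0 the scheme is exactly the
classical multiplicative NMF iteration, which the test-suite verifies to
1e−12 over 25 iterations.

Consequences verified by tests: non-negativity is preserved by every step;
the objective trace is non-increasing (slack 1e−8 for roundoff and the ε
guard) across a grid of α ∈ {0, 1, 10} and c ∈ {0.1, 0.5, 1}.

### Initialization, restarts, convergence

- **U**, **V** start uniform on (0, 1] scaled by √(mean(X)/k), seeded.
- The objective is non-convex, so `fit` runs `n_init = 5` seeded restarts
  and keeps the run with the lowest final objective (ties by restart
  index). Selection is by the model's own objective only. A single start
  occasionally lands in a minimum that spends a factor on an outlier group.
- Convergence is declared at a joint fixed point of the alternating
  scheme: relative objective change < tol *and* every auxiliary weight
  changes by < tol between iterations (default tol = 1e−4, cap
  max_iter = 100). The weight condition makes `omega` in the result — the
  weights used in the final updates — reproducible from the final factors
  to within tol, which the acceptance suite checks. An objective-only rule
  leaves the weights drifting by a small problem-dependent multiple of tol.
- ε = 1e−10 guards all update denominators; the exact multiplicative rules
  divide without guards.
- Non-finite factors or objective values abort with the iteration index.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| k (rank) | required | number of latent programs; set to the expected number of cell populations for clustering |
| c | 0.5 | Cauchy scale, in the units of a cell column's residual norm; the model is reported to be insensitive over a wide range |
| α | 10.0 | hypergraph regularization weight |
| p | 5 | neighbors per hyperedge |
| σ | mean pairwise distance | affinity bandwidth |
| n_init | 5 | random restarts, best objective kept |
| max_iter / tol | 100 / 1e−4 | stopping rule (joint fixed point, above) |

No internal log-transform or normalization is applied: distances and
residuals are computed on the matrix as given, and `--log1p` /
`--gene-filter-min-cells` are exposed as explicit opt-in preprocessing
flags in the readers and CLI.

## Downstream analysis

**Clustering.** K-means (k-means++ seeding, 20 restarts, seeded) on the
cell columns of **V**.

**Scoring.** NMI with arithmetic-mean normalization and the Hubert–Arabie
adjusted Rand index, delegated to scikit-learn behind this package's
validation layer; both agree with brute-force contingency/pair-counting
implementations to 1e−12 in the tests. Degenerate conventions: identical
partitions always score 1, including the trivial single-cluster case.

**Marker ranking.** Pearson correlation between coefficient columns
(negatives clipped to 0 so graph weights stay non-negative; zero-variance
columns get similarity 0 with a warning) defines a cell similarity; a
symmetrized kNN graph (default knn = 5, independent of the factorization's
p) gives L_g = D − W, and each gene's expression vector f is scored by
(f̃ᵀ L_g f̃)/(f̃ᵀ D f̃) after degree-weighted centering — the He–Cai–Niyogi
Laplacian Score. Scores are affine-invariant per gene; constant genes get
the worst score 1 with a warning. Genes are ranked ascending (low score =
varies between clusters but not between neighbors = marker-like); the
opposite direction is exposed as a flag because both conventions circulate.

## Synthetic benchmark generator

`SyntheticSpec`/`generate` emulate the regime the method targets:
X = U_true·V_true + Gaussian noise clipped at 0, with U_true a U(0, 0.5)
background plus per-cluster blocks of `marker_genes_per_cluster` genes
elevated by `signal_strength`, and V_true a cluster-indicator plus U(0,
0.05) background — so the clean matrix has rank ≤ the number of clusters,
and clipping plus block structure induce sparsity. Contamination replaces
an `outlier_fraction` of whole cells with log-normal noise
(median `outlier_scale`, σ_log = 1): the cell-level reading matches the
per-column down-weighting ω_j of the loss. Outlier cells keep their
original truth label — contamination corrupts the measurement, not the
identity — which caps the achievable ARI at roughly 0.81 when 10% of cells
are contaminated and assigned arbitrarily.

Defaults (200 genes × 120 cells, 3 balanced clusters, signal 5, noise sd
0.5 = 10% of signal, 10 markers per cluster, contamination off) are the
standard benchmark condition used throughout the tests; robustness studies
switch contamination to 10%. The generator makes no attempt at realistic
scRNA-seq count models (negative-binomial dropout, library-size effects),
so passing tests demonstrate robustness to heavy-tailed whole-cell
corruption, not performance on any real accession.

Problem sizes in the tests and acceptance script (20 replicates of
200 × 120 for the studies; 20–50 instances of ≤ 40 cells for the
structural checks) were chosen so the entire suite runs in well under a
minute while keeping the studies' means stable to ~0.01.

## Known limitations

- The objective settles in two phases: the hypergraph penalty collapses
  within ~3 iterations, but the Cauchy loss then improves slowly for
  another ~30–50 iterations while the factors find the cluster structure.
  The objective after 5 iterations is typically ~40% above its value at
  iteration 100 on the default benchmark, so runs stopped very early
  retain most of the final clustering quality only sometimes — let the
  stopping rule decide.
- With c far below the typical residual norm, all cells sit in the
  saturated regime of the loss and the effective step sizes are small;
  convergence is slow (the restarts mitigate the induced local-minimum
  risk).
- Dense linear algebra throughout: intended for matrices up to a few
  thousand cells; no sparse/GPU/minibatch path.
- Rank selection, alternative robust losses (L2,1, correntropy), and
  normalized hypergraph Laplacians are out of scope.
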