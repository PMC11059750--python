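"""Synthetic expression matrices with planted populations and outlier cells.

The generator emulates the regime the method targets: a low-rank non-negative
signal (k cell populations, each with a block of elevated marker genes),
additive Gaussian measurement noise clipped at zero (which also induces
sparsity), and a contaminating fraction of cells replaced wholesale by
heavy-tailed log-normal noise — the "outlier cell" that a robust loss should
down-weight.  It makes no attempt at realistic scRNA-seq count models
(negative-binomial dropout etc.); it exists so every pipeline stage is
testable without downloading accessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .evaluation import ClusterLabels
from .io import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of the generator.

    Defaults describe the standard benchmark condition used throughout the
    test-suite: 200 genes x 120 cells in 3 balanced populations, marker
    blocks elevated by ``signal_strength`` = 5 over a U(0, 0.5) background,
    and Gaussian noise at 10% of the signal.  Contamination is off by
    default; robustness studies switch it on (typically
    ``outlier_fraction = 0.1``), replacing that fraction of cells with
    log-normal outliers of median scale ``outlier_scale`` = 10.
    """

    n_genes: int = 200
    n_cells: int = 120
    n_clusters: int = 3
    signal_strength: float = 5.0
    noise_sd: float = 0.5
    outlier_fraction: float = 0.0
    outlier_scale: float = 10.0
    marker_genes_per_cluster: int = 10
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_cells, self.n_clusters) < 1:
            raise InvalidParameterError("dimensions must be positive")
        if self.n_clusters > self.n_cells:
            raise InvalidParameterError(
                f"{self.n_clusters} clusters for {self.n_cells} cells"
            )
        if self.marker_genes_per_cluster * self.n_clusters > self.n_genes:
            raise InvalidParameterError(
                f"{self.marker_genes_per_cluster} markers x {self.n_clusters} "
                f"clusters exceeds {self.n_genes} genes"
            )
        if not 0 <= self.outlier_fraction < 1:
            raise InvalidParameterError(
                f"outlier_fraction must be in [0, 1), got {self.outlier_fraction}"
            )
        if self.signal_strength <= 0 or self.outlier_scale <= 0:
            raise InvalidParameterError("signal and outlier scales must be positive")
        if self.noise_sd < 0 or self.marker_genes_per_cluster < 0:
            raise InvalidParameterError("noise_sd and marker count must be >= 0")


def generate(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, ClusterLabels, list[str]]:
    """Draw one synthetic dataset: matrix, truth labels, planted marker ids.

    Construction: ``X = U_true V_true + noise`` clipped at 0.  ``U_true`` has
    a U(0, 0.5) background with cluster-specific marker blocks raised by
    ``signal_strength``; ``V_true`` is a cluster-indicator matrix plus a
    U(0, 0.05) background, so the clean matrix has rank <= ``n_clusters``.
    Outlier cells keep their original truth label — contamination replaces
    the measurement, not the cell's identity.  Deterministic per spec + seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m, n, k = spec.n_genes, spec.n_cells, spec.n_clusters

    labels = np.arange(n) % k  # balanced: sizes differ by <= 1
    rng.shuffle(labels)

    U_true = rng.uniform(0.0, 0.5, size=(m, k))
    nm = spec.marker_genes_per_cluster
    marker_ids: list[str] = []
    for t in range(k):
        rows = np.arange(t * nm, (t + 1) * nm)
        U_true[rows, t] += spec.signal_strength
        marker_ids.extend(f"gene_{r}" for r in rows)

    V_true = rng.uniform(0.0, 0.05, size=(k, n))
    V_true[labels, np.arange(n)] += 1.0

    X = U_true @ V_true
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=(m, n))
    X = np.clip(X, 0.0, None)

    n_out = int(np.floor(spec.outlier_fraction * n))
    if n_out > 0:
        out_cells = rng.choice(n, size=n_out, replace=False)
        X[:, out_cells] = rng.lognormal(
            mean=np.log(spec.outlier_scale), sigma=1.0, size=(m, n_out)
        )

    expr = ExpressionMatrix(
        X,
        gene_ids=[f"gene_{i}" for i in range(m)],
        cell_ids=[f"cell_{j}" for j in range(n)],
    )
    return expr, ClusterLabels(labels=labels, n_clusters=k), marker_ids
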