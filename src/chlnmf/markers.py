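"""Marker-gene ranking by Laplacian Score on a learned cell-similarity graph.

After factorization, cells with similar coefficient columns are biologically
similar; Pearson correlation between columns of ``V`` gives a cell-cell
similarity (negative correlations clipped to 0 so graph weights stay
non-negative).  A k-nearest-neighbor graph weighted by that similarity
defines a graph Laplacian ``L_g = D - W``, and each gene ``r`` with
expression vector ``f_r`` across cells is scored by

    score_r = (f~_r^T L_g f~_r) / (f~_r^T D f~_r),

where ``f~_r`` is ``f_r`` centered by its degree-weighted mean.  A low score
means the gene varies little between neighboring cells while varying overall
— it respects the cluster structure, the signature of a marker.  Genes are
therefore ranked ascending by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .io import ExpressionMatrix

__all__ = ["MarkerRanking", "pearson_similarity", "laplacian_score", "top_markers"]


@dataclass
class MarkerRanking:
    """Per-gene Laplacian Scores plus the ordered top-``top_n`` marker list."""

    gene_ids: list[str]
    scores: np.ndarray
    order: np.ndarray
    top_n: int

    @property
    def top(self) -> list[str]:
        return [self.gene_ids[i] for i in self.order[: self.top_n]]


def pearson_similarity(V: np.ndarray) -> np.ndarray:
    """Pearson correlation between cell columns of ``V``, clipped at 0.

    Zero-variance columns get similarity 0 to every other cell (with a
    warning); the diagonal is always 1.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] < 2:
        raise InvalidInputError("V must be 2-D with at least 2 cell columns")
    n = V.shape[1]
    sd = V.std(axis=0)
    degenerate = sd <= 1e-12 * max(1.0, float(np.abs(V).max()))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance cell column(s); their "
            "similarities are set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(V.T)
    C = np.where(np.isfinite(C), C, 0.0)
    C[degenerate, :] = 0.0
    C[:, degenerate] = 0.0
    C = np.clip(C, 0.0, 1.0)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return C


def _knn_graph(S: np.ndarray, knn: int) -> np.ndarray:
    """Symmetrized kNN graph weighted by ``S`` (self-loops excluded)."""
    n = S.shape[0]
    knn = min(knn, n - 1)
    W = np.zeros_like(S)
    idx = np.arange(n)
    for i in range(n):
        s = S[i].copy()
        s[i] = -np.inf
        order = np.lexsort((idx, -s))
        nb = order[:knn]
        W[i, nb] = S[i, nb]
    return np.maximum(W, W.T)


def laplacian_score(
    X: ExpressionMatrix | np.ndarray,
    S_cells: np.ndarray,
    knn: int = 5,
) -> np.ndarray:
    """Laplacian Score of every gene on the kNN graph built from ``S_cells``.

    Constant genes (zero degree-weighted variance) receive the worst score 1
    with a warning.  Raises if the graph has no edges at all.
    """
    F = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    n = F.shape[1]
    if S_cells.shape != (n, n):
        raise InvalidInputError(
            f"similarity is {S_cells.shape} but X has {n} cells"
        )
    if knn < 1:
        raise InvalidParameterError(f"knn must be >= 1, got {knn}")
    W = _knn_graph(S_cells, knn)
    d = W.sum(axis=1)
    if d.sum() == 0:
        raise InvalidInputError("similarity graph has no edges (all weights 0)")
    L = np.diag(d) - W
    mu = (F @ d) / d.sum()  # degree-weighted mean per gene
    Fc = F - mu[:, None]
    num = np.einsum("rj,jk,rk->r", Fc, L, Fc)
    den = (Fc**2) @ d
    scores = np.ones(F.shape[0])
    ok = den > 1e-12 * max(1.0, float(np.abs(F).max()) ** 2)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} constant gene(s) assigned worst score 1",
            stacklevel=2,
        )
    scores[ok] = num[ok] / den[ok]
    # quadratic forms can dip a hair below 0 through roundoff
    return np.maximum(scores, 0.0)


def top_markers(
    scores: np.ndarray,
    gene_ids: list[str],
    top_n: int = 10,
    ascending: bool = True,
) -> MarkerRanking:
    """Rank genes by Laplacian Score and return the leading ``top_n``.

    Ascending order (low score = most locality-preserving = most important)
    is the standard reading; ``ascending=False`` exposes the opposite one.
    Ties are broken by gene identifier.
    """
    scores = np.asarray(scores, dtype=float)
    if len(gene_ids) != scores.size:
        raise InvalidInputError(
            f"{len(gene_ids)} gene ids for {scores.size} scores"
        )
    if top_n <= 0:
        raise InvalidParameterError(f"top_n must be positive, got {top_n}")
    key = scores if ascending else -scores
    order = np.array(
        sorted(range(scores.size), key=lambda i: (key[i], gene_ids[i]))
    )
    return MarkerRanking(
        gene_ids=list(gene_ids),
        scores=scores,
        order=order,
        top_n=min(top_n, scores.size),
    )
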