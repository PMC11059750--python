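"""Cell-level hypergraph construction and its unnormalized Laplacian.

A hypergraph generalizes a graph: each hyperedge joins an arbitrary subset of
vertices, so a single edge can record the joint neighborhood of a cell rather
than one pairwise relation.  Here every cell ``i`` seeds one hyperedge
``e_i = {i} + its p most-affine neighbors``, affinities coming from a
Gaussian kernel on Euclidean distances between expression profiles:

    A_ij = exp(-||x_i - x_j||^2 / sigma^2)

with ``sigma`` defaulting to the mean pairwise distance.  Hyperedge weights
sum the seed's affinities over the edge members (the seed itself included,
contributing ``A_ii = 1``).  With incidence ``H`` (vertices x edges), weight
diagonal ``W`` and edge-degree diagonal ``D_e``, the vertex-similarity matrix
is ``S = H W D_e^{-1} H^T`` and the unnormalized hypergraph Laplacian is

    L = D_v - S,

which is symmetric positive semi-definite with zero row sums.  Its quadratic
form penalizes coefficient differences among cells sharing hyperedges, which
is exactly how it enters the factorization objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidInputError, InvalidParameterError, NumericalError
from .io import ExpressionMatrix

__all__ = [
    "AffinityMatrix",
    "Hypergraph",
    "affinity_matrix",
    "build_hyperedges",
    "hyperedge_weights",
    "degrees",
    "laplacian",
    "build_hypergraph",
]

# store incidence sparsely above this many cells; dense maths elsewhere
_SPARSE_THRESHOLD = 1000


@dataclass
class AffinityMatrix:
    """Symmetric Gaussian-kernel cell affinity with the bandwidth used."""

    values: np.ndarray
    sigma: float


@dataclass
class Hypergraph:
    """Incidence, weights, degrees, similarity and Laplacian of a hypergraph.

    ``incidence`` is vertices x edges binary (edge ``j`` is seeded at cell
    ``j``); ``weights`` holds one positive weight per edge;
    ``vertex_degrees`` / ``edge_degrees`` are the diagonals of D_v and D_e.
    ``similarity`` and ``laplacian`` are filled in by :func:`laplacian`.
    """

    incidence: np.ndarray | scipy.sparse.spmatrix
    weights: np.ndarray | None = None
    vertex_degrees: np.ndarray | None = None
    edge_degrees: np.ndarray | None = None
    similarity: np.ndarray | None = None
    laplacian: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.incidence.shape[0]

    def incidence_dense(self) -> np.ndarray:
        H = self.incidence
        return H.toarray() if scipy.sparse.issparse(H) else np.asarray(H)


def _cell_matrix(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def affinity_matrix(
    X: ExpressionMatrix | np.ndarray, sigma: float | None = None
) -> AffinityMatrix:
    """Gaussian-kernel affinity between cell columns of ``X``.

    When ``sigma`` is omitted it is set to the mean of all pairwise Euclidean
    distances between distinct cells ("average separation").
    """
    V = _cell_matrix(X)
    n = V.shape[1]
    if n < 2:
        raise InvalidInputError(f"need at least 2 cells, got {n}")
    if sigma is not None and sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    sq = squareform(pdist(V.T, metric="sqeuclidean"))
    if sigma is None:
        mean_dist = float(np.sqrt(sq)[np.triu_indices(n, 1)].mean())
        if mean_dist == 0.0:
            raise InvalidInputError(
                "all cells are identical (mean pairwise distance is 0); "
                "the Gaussian bandwidth is undefined for this degenerate geometry"
            )
        sigma = mean_dist
    A = np.exp(-sq / sigma**2)
    # enforce exact symmetry / unit diagonal against roundoff
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 1.0)
    return AffinityMatrix(values=A, sigma=float(sigma))


def build_hyperedges(A: AffinityMatrix, p: int) -> Hypergraph:
    """One hyperedge per cell: the cell plus its ``p`` most-affine neighbors.

    Neighbor ties are broken by ascending cell index so the construction is
    deterministic.  Returns a :class:`Hypergraph` carrying incidence only.
    """
    Av = A.values
    n = Av.shape[0]
    if not 1 <= p <= n - 1:
        raise InvalidParameterError(f"p must be in [1, {n - 1}], got {p}")
    H = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        aff = Av[i].copy()
        aff[i] = -np.inf  # self excluded from the neighbor ranking
        order = np.lexsort((idx, -aff))
        members = order[:p]
        H[i, i] = 1.0
        H[members, i] = 1.0
    if n > _SPARSE_THRESHOLD:
        return Hypergraph(incidence=scipy.sparse.csr_matrix(H))
    return Hypergraph(incidence=H)


def hyperedge_weights(A: AffinityMatrix, G: Hypergraph) -> np.ndarray:
    """Initial weight of edge ``e_i``: sum of affinities ``A_ij`` over members.

    The seed's self-term ``A_ii = 1`` is included, so weights are strictly
    positive.
    """
    H = G.incidence_dense()
    # w(e_i) = sum_j in e_i A_ij  ==  column i of H dotted with row i of A
    w = np.einsum("ji,ij->i", H, A.values)
    G.weights = w
    return w


def degrees(G: Hypergraph) -> tuple[np.ndarray, np.ndarray]:
    """Vertex degrees d(v) = sum_e w(e) H(v,e) and edge degrees |e|."""
    if G.weights is None:
        raise InvalidInputError("hyperedge weights not built")
    H = G.incidence_dense()
    d_e = H.sum(axis=0)
    if np.any(d_e == 0):
        e = int(np.argmin(d_e))
        raise NumericalError(f"hyperedge {e} is empty; D_e is singular")
    d_v = H @ G.weights
    G.vertex_degrees, G.edge_degrees = d_v, d_e
    return d_v, d_e


def laplacian(G: Hypergraph) -> tuple[np.ndarray, np.ndarray]:
    """Similarity ``S = H W D_e^{-1} H^T`` and Laplacian ``L = D_v - S``."""
    if G.vertex_degrees is None or G.edge_degrees is None:
        degrees(G)
    H = G.incidence_dense()
    S = (H * (G.weights / G.edge_degrees)) @ H.T
    L = np.diag(G.vertex_degrees) - S
    L = 0.5 * (L + L.T)
    G.similarity, G.laplacian = S, L
    return S, L


def build_hypergraph(
    X: ExpressionMatrix | np.ndarray,
    p: int = 5,
    sigma: float | None = None,
) -> Hypergraph:
    """Affinity -> hyperedges -> weights -> degrees -> Laplacian, in one call."""
    A = affinity_matrix(X, sigma=sigma)
    G = build_hyperedges(A, p)
    hyperedge_weights(A, G)
    degrees(G)
    laplacian(G)
    return G
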