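"""K-means on the coefficient matrix and partition-agreement metrics.

Cell types are called by running K-means on the columns of the learned
coefficient matrix ``V`` (each cell's k-dimensional loading).  Partitions are
scored against reference labels with NMI — mutual information normalized by
the arithmetic mean of the two entropies — and the Hubert–Arabie adjusted
Rand index, which chance-corrects pair-counting agreement into [-1, 1].
Both metrics delegate to scikit-learn; this module fixes the normalization
variant, the degenerate-partition conventions (identical trivial partitions
score 1), and input validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["ClusterLabels", "kmeans_cluster", "nmi", "ari"]


@dataclass
class ClusterLabels:
    """An integer labelling of cells into ``n_clusters`` groups."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise InvalidInputError("labels must be a 1-D vector")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_clusters
        ):
            raise InvalidInputError(
                f"labels must lie in [0, {self.n_clusters}), got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )


def _label_vector(x: ClusterLabels | np.ndarray) -> np.ndarray:
    return x.labels if isinstance(x, ClusterLabels) else np.asarray(x, dtype=int)


def kmeans_cluster(
    V: np.ndarray, n_clusters: int, seed: int = 0, n_restarts: int = 20
) -> ClusterLabels:
    """K-means over the cell columns of ``V``, best of ``n_restarts``.

    Uses k-means++ seeding; deterministic given ``seed``.
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    if not 1 <= n_clusters <= n:
        raise InvalidParameterError(
            f"n_clusters must be in [1, {n}], got {n_clusters}"
        )
    if not np.isfinite(V).all():
        raise InvalidInputError("V contains non-finite entries")
    km = KMeans(
        n_clusters=n_clusters,
        n_init=n_restarts,
        random_state=seed,
    ).fit(V.T)
    return ClusterLabels(labels=km.labels_, n_clusters=n_clusters)


def _check_pair(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    t, p = _label_vector(truth), _label_vector(pred)
    if t.shape != p.shape:
        raise InvalidInputError(
            f"label vectors differ in length: {t.size} vs {p.size}"
        )
    return t, p


def nmi(truth: ClusterLabels | np.ndarray, pred: ClusterLabels | np.ndarray) -> float:
    """Normalized mutual information, arithmetic-mean normalization.

    ``M(Q,J) / ((IE(Q) + IE(J)) / 2)`` over the contingency table; 1 for
    identical partitions, 0 for independent ones.  When both partitions are
    a single cluster the ratio is 0/0 and is defined as 1 (the partitions are
    then identical).
    """
    t, p = _check_pair(truth, pred)
    return float(normalized_mutual_info_score(t, p, average_method="arithmetic"))


def ari(truth: ClusterLabels | np.ndarray, pred: ClusterLabels | np.ndarray) -> float:
    """Hubert–Arabie adjusted Rand index in [-1, 1]; 1 iff partitions agree.

    Degenerate partitions (both trivial) score 1 when equal, matching the
    convention that a partition always agrees perfectly with itself.
    """
    t, p = _check_pair(truth, pred)
    return float(adjusted_rand_score(t, p))
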