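"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over definitions — deliberately
naive and slow — so that agreement with the package is a genuine two-route
check rather than a reimplementation of the same code path.
"""

from itertools import combinations
from math import comb, log

import numpy as np


def naive_objective(X, U, V, L, alpha, c):
    """Per-column Cauchy loss + hypergraph quadratic form, by explicit loops."""
    m, n = X.shape
    total = 0.0
    for j in range(n):
        r2 = 0.0
        for i in range(m):
            pred = 0.0
            for k in range(U.shape[1]):
                pred += U[i, k] * V[k, j]
            r2 += (X[i, j] - pred) ** 2
        total += log(1.0 + r2 / c**2)
    if L is not None and alpha > 0:
        for k in range(V.shape[0]):
            for i in range(n):
                for j in range(n):
                    total += alpha * V[k, i] * L[i, j] * V[k, j]
    return total


def naive_update_U(X, U, V, omega, eps=1e-10):
    m, k, n = U.shape[0], U.shape[1], V.shape[1]
    out = np.empty_like(U)
    for i in range(m):
        for a in range(k):
            num = sum(X[i, j] * omega[j] * V[a, j] for j in range(n))
            den = sum(
                sum(U[i, b] * V[b, j] for b in range(k)) * omega[j] * V[a, j]
                for j in range(n)
            )
            out[i, a] = U[i, a] * num / (den + eps)
    return out


def naive_update_V(X, U, V, omega, S, d_v, alpha, eps=1e-10):
    m, k, n = U.shape[0], U.shape[1], V.shape[1]
    out = np.empty_like(V)
    for a in range(k):
        for j in range(n):
            num = sum(U[i, a] * X[i, j] for i in range(m)) * omega[j]
            den = sum(
                sum(U[i, a] * U[i, b] for i in range(m)) * V[b, j]
                for b in range(k)
            ) * omega[j]
            if alpha > 0:
                num += 2.0 * alpha * sum(V[a, t] * S[t, j] for t in range(n))
                den += 2.0 * alpha * V[a, j] * d_v[j]
            out[a, j] = V[a, j] * num / (den + eps)
    return out


def textbook_nmf_step(X, U, V, eps=1e-10):
    """One classical multiplicative Frobenius-NMF iteration."""
    U = U * (X @ V.T) / (U @ V @ V.T + eps)
    V = V * (U.T @ X) / (U.T @ U @ V + eps)
    return U, V


def brute_force_ari(a, b):
    """Hubert–Arabie adjusted Rand index by explicit pair counting."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    ss = sd = ds = dd = 0
    for i, j in combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    idx = ss
    sum_a = sum(comb(int(c), 2) for c in np.bincount(np.unique(a, return_inverse=True)[1]))
    sum_b = sum(comb(int(c), 2) for c in np.bincount(np.unique(b, return_inverse=True)[1]))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:
        return 1.0 if np.array_equal(
            np.unique(a, return_inverse=True)[1],
            np.unique(b, return_inverse=True)[1],
        ) else 0.0
    return (idx - expected) / (maximum - expected)


def brute_force_nmi(a, b):
    """NMI (arithmetic-mean normalization) from the contingency table."""
    a = np.unique(a, return_inverse=True)[1]
    b = np.unique(b, return_inverse=True)[1]
    n = a.size
    ka, kb = a.max() + 1, b.max() + 1
    cont = np.zeros((ka, kb))
    for i in range(n):
        cont[a[i], b[i]] += 1
    pa, pb = cont.sum(axis=1) / n, cont.sum(axis=0) / n
    mi = 0.0
    for i in range(ka):
        for j in range(kb):
            pij = cont[i, j] / n
            if pij > 0:
                mi += pij * log(pij / (pa[i] * pb[j]))
    ha = -sum(p * log(p) for p in pa if p > 0)
    hb = -sum(p * log(p) for p in pb if p > 0)
    if ha + hb == 0.0:
        return 1.0  # both partitions trivial, hence identical
    return mi / ((ha + hb) / 2)


def naive_laplacian_score(F, W):
    """Laplacian Scores from an explicit weighted graph, gene by gene."""
    n = W.shape[0]
    d = W.sum(axis=1)
    L = np.diag(d) - W
    one = np.ones(n)
    scores = []
    for f in F:
        ft = f - (f @ d) / (one @ d) * one
        den = ft @ np.diag(d) @ ft
        if den <= 1e-12 * max(1.0, float(np.abs(F).max()) ** 2):
            scores.append(1.0)
        else:
            scores.append(max(ft @ L @ ft / den, 0.0))
    return np.array(scores)


def naive_pearson(V):
    """Column-wise Pearson correlation by the direct covariance formula."""
    n = V.shape[1]
    C = np.eye(n)
    for i in range(n):
        for j in range(n):
            xi, xj = V[:, i], V[:, j]
            ci, cj = xi - xi.mean(), xj - xj.mean()
            den = np.sqrt((ci**2).sum() * (cj**2).sum())
            C[i, j] = (ci * cj).sum() / den if den > 0 else 0.0
    return C
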