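"""Robust NMF with a Cauchy loss and hypergraph regularization.

The model factorizes a non-negative genes x cells matrix ``X`` as ``U V``
(``U``: genes x k basis of gene programs, ``V``: k x cells coefficients) by
minimizing, over ``U, V >= 0``,

    sum_j ln(1 + ||x_j - U v_j||^2 / c^2)  +  alpha * Tr(V L V^T)

where the sum runs over cell columns, ``c`` is the Cauchy scale and ``L`` is
the unnormalized hypergraph Laplacian over cells.  The logarithm grows slowly
in the residual, so a heavily corrupted cell contributes bounded influence —
the robustness that a Frobenius loss lacks.

Optimization is half-quadratic: introducing one auxiliary weight per cell,

    omega_j = 2 / (c^2 + ||x_j - U v_j||^2),

turns the robust loss into a column-weighted quadratic, and with
``Lam = diag(omega)`` the factors follow multiplicative updates

    U <- U * (X Lam V^T) / (U V Lam V^T)
    V <- V * (U^T X Lam + alpha V S) / (U^T U V Lam + alpha V D_v)

which preserve non-negativity and never increase the objective.  With
``omega`` frozen at ones and ``alpha = 0`` the scheme reduces exactly to the
classical multiplicative NMF rules; :func:`nmf` provides that baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, NumericalError
from .hypergraph import Hypergraph
from .io import ExpressionMatrix

__all__ = [
    "FactorizationConfig",
    "FactorizationResult",
    "cauchy_loss",
    "objective",
    "hq_weights",
    "update_U",
    "update_V",
    "fit",
    "nmf",
]


@dataclass
class FactorizationConfig:
    """Hyperparameters of the solver.

    rank
        Number of latent factors k; must satisfy ``k < min(genes, cells)``.
    cauchy_scale
        Scale ``c`` of the Cauchy loss; residuals far beyond ``c`` are
        down-weighted.  Default 0.5.
    alpha
        Weight of the hypergraph regularizer.  Default 10.0.
    neighborhood
        Neighbors per hyperedge when the hypergraph is built implicitly.
    max_iter, tol
        Iteration cap and relative objective-change threshold.
    n_init
        Number of seeded random restarts; the run with the lowest final
        objective wins.  The objective is non-convex, so a single start can
        land in a poor local minimum; restarts are the standard remedy.
    eps
        Additive guard in update denominators.
    """

    rank: int
    cauchy_scale: float = 0.5
    alpha: float = 10.0
    neighborhood: int = 5
    max_iter: int = 100
    tol: float = 1e-4
    n_init: int = 5
    seed: int = 0
    eps: float = 1e-10

    def validate(self, n_genes: int, n_cells: int) -> None:
        if not 1 <= self.rank < min(n_genes, n_cells):
            raise InvalidParameterError(
                f"rank must be in [1, {min(n_genes, n_cells) - 1}] for a "
                f"{n_genes} x {n_cells} matrix, got {self.rank}"
            )
        if self.cauchy_scale <= 0:
            raise InvalidParameterError(
                f"cauchy_scale must be positive, got {self.cauchy_scale}"
            )
        if self.alpha < 0:
            raise InvalidParameterError(f"alpha must be >= 0, got {self.alpha}")
        for name in ("max_iter", "neighborhood", "n_init"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if self.tol <= 0 or self.eps <= 0:
            raise InvalidParameterError("tol and eps must be positive")


@dataclass
class FactorizationResult:
    """Learned factors plus diagnostics.

    ``omega`` holds the final half-quadratic weight of each cell — small
    values flag cells the Cauchy loss judged outlying.  ``objective_trace``
    starts at the initial objective and appends one value per iteration.
    """

    U: np.ndarray
    V: np.ndarray
    omega: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    config: FactorizationConfig | None = field(default=None, repr=False)


def _as_array(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    return X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)


def cauchy_loss(x: float | np.ndarray, c: float) -> float | np.ndarray:
    """Cauchy loss ``ln(1 + x^2/c^2)``: even, increasing in |x|, log growth."""
    if c <= 0:
        raise InvalidParameterError(f"cauchy scale c must be positive, got {c}")
    x = np.asarray(x, float)
    out = np.log1p(x**2 / c**2)
    return float(out) if out.ndim == 0 else out


def _column_sq_residuals(X: np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    R = X - U @ V
    return np.einsum("ij,ij->j", R, R)


def objective(
    X: ExpressionMatrix | np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    L: np.ndarray | None,
    alpha: float,
    c: float,
) -> float:
    """Cauchy reconstruction loss (per cell column) + hypergraph penalty."""
    X = _as_array(X)
    if c <= 0:
        raise InvalidParameterError(f"cauchy scale c must be positive, got {c}")
    if U.shape[0] != X.shape[0] or V.shape[1] != X.shape[1] \
            or U.shape[1] != V.shape[0]:
        raise InvalidInputError(
            f"shapes do not conform: X {X.shape}, U {U.shape}, V {V.shape}"
        )
    if (U < 0).any() or (V < 0).any():
        raise InvalidInputError("U and V must be non-negative")
    loss = float(np.sum(np.log1p(_column_sq_residuals(X, U, V) / c**2)))
    if alpha > 0 and L is not None:
        loss += alpha * float(np.einsum("ki,ij,kj->", V, L, V))
    return loss


def hq_weights(
    X: ExpressionMatrix | np.ndarray, U: np.ndarray, V: np.ndarray, c: float
) -> np.ndarray:
    """Half-quadratic weight per cell: ``omega_j = 2/(c^2 + ||x_j - U v_j||^2)``.

    Lies in ``(0, 2/c^2]``; an exactly reconstructed column attains the upper
    end, a wildly corrupted one tends to 0.
    """
    X = _as_array(X)
    return 2.0 / (c**2 + _column_sq_residuals(X, U, V))


def update_U(
    X: ExpressionMatrix | np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    omega: np.ndarray,
    eps: float = 1e-10,
) -> np.ndarray:
    """One multiplicative step on the basis: ``U * (X Lam V^T)/(U V Lam V^T)``."""
    X = _as_array(X)
    Vw = V * omega  # right-multiplication by Lam = diag(omega)
    return U * (X @ Vw.T) / (U @ (V @ Vw.T) + eps)


def update_V(
    X: ExpressionMatrix | np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    omega: np.ndarray,
    S: np.ndarray | None,
    d_v: np.ndarray | None,
    alpha: float,
    eps: float = 1e-10,
) -> np.ndarray:
    """One multiplicative step on the coefficients, with the hypergraph pull.

    ``V * (U^T X Lam + 2 alpha V S) / (U^T U V Lam + 2 alpha V D_v)``;
    ``d_v`` is the diagonal of D_v.  The graph terms carry the coefficient
    ``2 alpha`` because the gradient of ``alpha Tr(V L V^T)`` is
    ``2 alpha V L`` while the half-quadratic data term ``(1/2) omega_j
    ||x_j - U v_j||^2`` (the convention under which ``omega = 2/(c^2+r^2)``
    is the exact auxiliary minimizer) contributes its factor 2 into
    ``omega`` itself; only this pairing makes the update a true
    majorize-minimize step for the stated objective.  With ``alpha = 0``
    and constant ``omega`` this is the classical coefficient rule.
    """
    X = _as_array(X)
    num = (U.T @ X) * omega
    den = (U.T @ U) @ V * omega
    if alpha > 0:
        num = num + 2.0 * alpha * (V @ S)
        den = den + 2.0 * alpha * (V * d_v)
    return V * num / (den + eps)


def _init_factors(
    m: int, n: int, k: int, mean_x: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    # uniform (0,1] scaled so that (UV)_ij has roughly the data's mean
    scale = np.sqrt(max(mean_x, np.finfo(float).tiny) / k)
    U0 = (1.0 - rng.random((m, k))) * scale
    V0 = (1.0 - rng.random((k, n))) * scale
    return U0, V0


def fit(
    X: ExpressionMatrix | np.ndarray,
    G: Hypergraph | None,
    config: FactorizationConfig,
    U0: np.ndarray | None = None,
    V0: np.ndarray | None = None,
) -> FactorizationResult:
    """Run the half-quadratic solver until the objective stalls.

    Each iteration recomputes the cell weights ``omega`` from the current
    residuals, then takes one multiplicative step on ``U`` and one on ``V``.
    Convergence is declared when the scheme reaches a joint fixed point:
    the objective changes by less than ``tol * max(1, |previous|)`` *and*
    every auxiliary weight changes by less than ``tol`` — so at convergence
    the stored ``omega`` reproduces itself from the final factors.  ``G``
    may be ``None`` only when ``alpha = 0``.

    Initialization is seeded; of ``config.n_init`` random restarts the one
    reaching the lowest final objective is returned (ties broken by restart
    index).  Passing ``U0``/``V0`` overrides the initialization and disables
    restarts.
    """
    Xa = _as_array(X)
    if (U0 is None) != (V0 is None):
        raise InvalidInputError("pass both U0 and V0 or neither")
    if U0 is None and config.n_init > 1:
        seeds = np.random.SeedSequence(config.seed).generate_state(config.n_init)
        best: FactorizationResult | None = None
        for s in seeds:
            single = FactorizationConfig(**{**config.__dict__,
                                            "seed": int(s % 2**31),
                                            "n_init": 1})
            res = fit(Xa, G, single)
            if best is None or res.objective_trace[-1] < best.objective_trace[-1]:
                best = res
        best.config = config
        return best
    if (Xa < 0).any():
        raise InvalidInputError("X must be non-negative")
    m, n = Xa.shape
    config.validate(m, n)
    c, alpha, eps = config.cauchy_scale, config.alpha, config.eps
    if alpha > 0:
        if G is None:
            raise InvalidInputError("alpha > 0 requires a hypergraph")
        if G.laplacian is None:
            from .hypergraph import laplacian as _lap

            _lap(G)
        S, d_v, L = G.similarity, G.vertex_degrees, G.laplacian
        if L.shape[0] != n:
            raise InvalidInputError(
                f"hypergraph has {L.shape[0]} cells but X has {n}"
            )
    else:
        S = d_v = L = None

    if U0 is None:
        rng = np.random.default_rng(config.seed)
        U, V = _init_factors(m, n, config.rank, float(Xa.mean()), rng)
    else:
        U, V = np.array(U0, float), np.array(V0, float)

    trace = [objective(Xa, U, V, L, alpha, c)]
    omega = hq_weights(Xa, U, V, c)  # reported: the weights used in the last updates
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        U = update_U(Xa, U, V, omega, eps=eps)
        V = update_V(Xa, U, V, omega, S, d_v, alpha, eps=eps)
        if not (np.isfinite(U).all() and np.isfinite(V).all()):
            raise NumericalError(f"non-finite factor entries at iteration {it}")
        r2 = _column_sq_residuals(Xa, U, V)
        f = float(np.sum(np.log1p(r2 / c**2)))
        if alpha > 0:
            f += alpha * float(np.einsum("ki,ij,kj->", V, L, V))
        if not np.isfinite(f):
            raise NumericalError(f"non-finite objective at iteration {it}")
        omega_next = 2.0 / (c**2 + r2)
        prev = trace[-1]
        trace.append(f)
        if (
            abs(prev - f) < config.tol * max(1.0, abs(prev))
            and np.abs(omega_next - omega).max() < config.tol
        ):
            converged = True
            break
        omega = omega_next
    return FactorizationResult(
        U=U,
        V=V,
        omega=omega,
        objective_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
        config=config,
    )


def nmf(
    X: ExpressionMatrix | np.ndarray,
    rank: int,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    eps: float = 1e-10,
    U0: np.ndarray | None = None,
    V0: np.ndarray | None = None,
) -> FactorizationResult:
    """Classical Frobenius NMF by multiplicative updates (the baseline).

    ``U <- U * (X V^T)/(U V V^T)``, ``V <- V * (U^T X)/(U^T U V)``; same
    initialization scheme and stopping rule as :func:`fit`, squared-error
    objective in the trace.
    """
    Xa = _as_array(X)
    if (Xa < 0).any():
        raise InvalidInputError("X must be non-negative")
    m, n = Xa.shape
    if not 1 <= rank < min(m, n):
        raise InvalidParameterError(f"rank {rank} out of range for {m} x {n}")
    rng = np.random.default_rng(seed)
    Ui, Vi = _init_factors(m, n, rank, float(Xa.mean()), rng)
    U = Ui if U0 is None else np.array(U0, float)
    V = Vi if V0 is None else np.array(V0, float)
    trace = [float(np.linalg.norm(Xa - U @ V) ** 2)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = U * (Xa @ V.T) / (U @ (V @ V.T) + eps)
        V = V * (U.T @ Xa) / ((U.T @ U) @ V + eps)
        f = float(np.linalg.norm(Xa - U @ V) ** 2)
        prev = trace[-1]
        trace.append(f)
        if abs(prev - f) < tol * max(1.0, abs(prev)):
            converged = True
            break
    return FactorizationResult(
        U=U,
        V=V,
        omega=np.ones(n),
        objective_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
    )
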