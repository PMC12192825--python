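"""Weighted neighborhood-preserving ensemble embedding (WNPEE).

A linear projection that preserves local structure across an *ensemble* of
KNN graphs instead of the single graph used by plain NPE.  For data
``X ∈ R^{D×N}`` (features in rows, samples in columns) and graphs with
neighborhood sizes ``k_1 < k_2 < ...``:

1. each graph's reconstruction weights ``W_k`` solve the LLE-style local Gram
   systems, row-stochastic over each sample's neighbors;
2. the projection ``A ∈ R^{D×d}`` solves the generalized eigenproblem
   ``X M Xᵀ a = λ (X Xᵀ + εI) a`` for the d smallest eigenvalues, where
   ``M = Σ_k α_k^r (I − W_k)ᵀ(I − W_k)`` is the ensemble reconstruction
   penalty;
3. the graph weights ``α`` (simplex, exponent r > 1) are re-estimated in
   closed form from the per-graph embedded-space losses,
   ``α_k ∝ tr_k^{-1/(r-1)}``.

Steps 2 and 3 each exactly minimize the joint objective
``J(A, α) = Σ_k α_k^r tr(AᵀX(I−W_k)ᵀ(I−W_k)XᵀA)`` (subject to the generalized
orthogonality constraint), so the recorded loss trace is non-increasing.
With a single graph the procedure reduces to plain NPE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


class NumericalError(RuntimeError):
    pass


#: Ridge scale for the local Gram systems (times tr(G)).
GRAM_RIDGE = 1e-3
#: Ridge scale for XXᵀ regularization (times tr(XXᵀ)/D).
GRAM_MATRIX_RIDGE = 1e-6


@dataclass
class GraphEnsemble:
    """KNN graphs over the N samples plus their reconstruction weights."""

    neighbors: list[np.ndarray]          # each (N, k_g) neighbor indices
    weight_matrices: list[sp.csr_matrix]  # each N×N row-stochastic over neighbors
    alphas: np.ndarray                    # simplex weights, one per graph
    r: float                              # ensemble control parameter (> 1)
    k_list: list[int]

    @property
    def n_graphs(self) -> int:
        return len(self.neighbors)


@dataclass
class EmbeddingModel:
    """Fitted WNPEE projection."""

    projection: np.ndarray   # (D, d), columns a_0..a_{d-1}
    embedded: np.ndarray     # (d, N) = projectionᵀ X
    M: np.ndarray            # (N, N) ensemble reconstruction penalty
    eigenvalues: np.ndarray  # (d,)
    ensemble: GraphEnsemble
    loss_trace: list[float] = field(default_factory=list)
    d: int = 0
    converged: bool = True

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new columns (features × samples) into the embedding."""
        return self.projection.T @ np.asarray(X, dtype=float)


def build_graph_ensemble(X: np.ndarray, k_list: list[int]) -> list[np.ndarray]:
    """Directed KNN graphs over the columns of ``X``.

    Graph g has an edge i→j iff j is among the k_g nearest Euclidean
    neighbors of i.  Ties are broken by smaller sample index (stable sort), so
    duplicated points give identical output across runs.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[1]
    k_list = list(k_list)
    if any(k <= 0 for k in k_list):
        raise ParameterError("neighborhood sizes must be positive")
    if any(b <= a for a, b in zip(k_list, k_list[1:])):
        raise ParameterError("k_list must be strictly increasing")
    if max(k_list) >= N:
        raise ParameterError(f"k={max(k_list)} requires more than {N} samples")
    D = cdist(X.T, X.T)
    np.fill_diagonal(D, np.inf)  # no self-edges
    order = np.argsort(D, axis=1, kind="stable")
    return [order[:, :k].copy() for k in k_list]


def reconstruction_weights(X: np.ndarray, neighbors: np.ndarray) -> sp.csr_matrix:
    """Row-stochastic LLE reconstruction weights for one graph.

    Row i minimizes ``||x_i − Σ_j W_ij x_j||²`` subject to ``Σ_j W_ij = 1``
    over the neighbors of i, via the local Gram system with ridge
    ``GRAM_RIDGE · tr(G) · I``.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[1]
    k = neighbors.shape[1]
    rows = np.repeat(np.arange(N), k)
    cols = neighbors.ravel()
    data = np.empty(N * k)
    for i in range(N):
        Z = X[:, neighbors[i]] - X[:, [i]]      # (D, k) centered neighbors
        G = Z.T @ Z
        trace = np.trace(G)
        ridge = GRAM_RIDGE * trace if trace > 0 else GRAM_RIDGE
        G = G + ridge * np.eye(k)
        try:
            w = scipy.linalg.solve(G, np.ones(k), assume_a="pos")
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericalError(f"singular Gram system at sample {i}") from exc
        s = w.sum()
        if s == 0 or not np.isfinite(s):  # pragma: no cover
            raise NumericalError(f"degenerate reconstruction weights at sample {i}")
        data[i * k : (i + 1) * k] = w / s
    W = sp.csr_matrix((data, (rows, cols)), shape=(N, N))
    return W


def per_graph_loss(Y: np.ndarray, W: sp.csr_matrix) -> float:
    """Embedded-space reconstruction loss ``tr(Yᵀ(I−W)ᵀ(I−W)Y)`` of one graph."""
    recon = (W @ Y.T).T  # Σ_j W_ij y_j for each sample i
    R = Y - np.asarray(recon)
    return float(np.sum(R * R))


def update_alphas(losses: np.ndarray, r: float) -> np.ndarray:
    """Closed-form simplex weights ``α_k ∝ (1/tr_k)^{1/(r−1)}``.

    Smaller per-graph loss ⇒ larger weight.  Graphs with exactly zero loss
    take the limit: all weight split equally among the zero-loss graphs.
    """
    losses = np.asarray(losses, dtype=float)
    if r <= 1:
        raise ParameterError("ensemble parameter r must be > 1")
    if np.any(losses < 0):
        raise ParameterError("per-graph losses must be non-negative")
    zero = losses == 0
    if zero.any():
        return zero / zero.sum()
    inv = losses ** (-1.0 / (r - 1.0))
    return inv / inv.sum()


def _ensemble_penalty(ensemble_Ws: list[sp.csr_matrix], alphas: np.ndarray,
                      r: float) -> np.ndarray:
    N = ensemble_Ws[0].shape[0]
    M = np.zeros((N, N))
    I = sp.identity(N, format="csr")
    for a, W in zip(alphas, ensemble_Ws):
        E = (I - W).toarray()
        M += (a ** r) * (E.T @ E)
    return M


def solve_embedding(
    X: np.ndarray,
    weight_matrices: list[sp.csr_matrix],
    alphas: np.ndarray,
    d: int,
    r: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Projection onto the d smallest generalized eigenvectors.

    Solves ``X M Xᵀ a = λ (X Xᵀ + εI) a`` with
    ``ε = GRAM_MATRIX_RIDGE · tr(XXᵀ)/D`` (rank-deficiency is the norm when
    D ≫ N).  Eigenvector signs are fixed by making each column's
    largest-magnitude entry positive.  Returns (A, Y, eigenvalues, M).
    """
    X = np.asarray(X, dtype=float)
    D, N = X.shape
    if not (0 < d < min(D, N)):
        raise ParameterError(f"d={d} must satisfy 0 < d < min(D, N)={min(D, N)}")
    M = _ensemble_penalty(weight_matrices, np.asarray(alphas, float), r)
    XXt = X @ X.T
    eps = GRAM_MATRIX_RIDGE * np.trace(XXt) / D
    if eps <= 0:
        eps = GRAM_MATRIX_RIDGE
    B = XXt + eps * np.eye(D)
    A_mat = X @ M @ X.T
    A_mat = 0.5 * (A_mat + A_mat.T)  # symmetrize against round-off
    try:
        eigvals, eigvecs = scipy.linalg.eigh(A_mat, B, subset_by_index=[0, d - 1])
    except scipy.linalg.LinAlgError as exc:
        cond = np.linalg.cond(B)
        raise NumericalError(
            f"generalized eigensolver failed (cond(B)={cond:.3e})"
        ) from exc
    # deterministic sign: largest-|entry| of each column positive
    flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    A = eigvecs * flip
    Y = A.T @ X
    return A, Y, eigvals, M


def default_k_list(n_samples: int) -> list[int]:
    ks = [k for k in (5, 10, 15) if k < n_samples]
    return ks or [max(1, n_samples - 1)]


def fit_wnpee(
    X: np.ndarray,
    k_list: list[int] | None = None,
    d: int | None = None,
    r: float = 2.0,
    max_iter: int = 30,
    tol: float = 1e-8,
) -> EmbeddingModel:
    """Alternating minimization of the ensemble embedding (Algorithm: fix W,
    iterate projection-solve and α-update until the loss change is < tol).

    Reconstruction weights are computed once per graph in the input space;
    only α and the projection iterate.  With ``tol=inf`` exactly one
    iteration runs.  Non-convergence at ``max_iter`` returns the last iterate
    with ``converged=False`` and a log warning.
    """
    X = np.asarray(X, dtype=float)
    D, N = X.shape
    if k_list is None:
        k_list = default_k_list(N)
    if d is None:
        d = max(1, min(20, N - 2, D - 1))
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")

    neighbors = build_graph_ensemble(X, k_list)
    Ws = [reconstruction_weights(X, nb) for nb in neighbors]
    Lg = len(Ws)
    alphas = np.full(Lg, 1.0 / Lg)

    loss_trace: list[float] = []
    A = Y = eigvals = M = None
    converged = False
    for _ in range(max_iter):
        A, Y, eigvals, M = solve_embedding(X, Ws, alphas, d, r)
        tr_k = np.array([per_graph_loss(Y, W) for W in Ws])
        alphas = update_alphas(tr_k, r)
        loss = float(np.sum(alphas**r * tr_k))
        loss_trace.append(loss)
        if len(loss_trace) >= 2 and abs(loss_trace[-2] - loss) < tol:
            converged = True
            break
        if tol == np.inf:
            break
    else:
        logger.warning("WNPEE did not converge in %d iterations", max_iter)

    ensemble = GraphEnsemble(
        neighbors=neighbors,
        weight_matrices=Ws,
        alphas=alphas,
        r=r,
        k_list=list(k_list),
    )
    return EmbeddingModel(
        projection=A,
        embedded=Y,
        M=M,
        eigenvalues=eigvals,
        ensemble=ensemble,
        loss_trace=loss_trace,
        d=d,
        converged=converged or tol == np.inf,
    )
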