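"""Logistic matrix factorization with KNN-graph-Laplacian (neighborhood)
regularization.

The model places microbes and diseases in a shared r-dimensional latent space
and scores a pair by the sigmoid of the latent inner product. Known positives
are up-weighted c-fold in the Bernoulli likelihood; the training set is either
positives plus a supplied reliable-negative set, or positives plus all
unlabeled pairs. L2 shrinkage and a graph-Laplacian penalty over each entity's
K nearest similarity neighbors regularize the factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "LmfConfig",
    "LatentFactors",
    "build_laplacian",
    "build_weights",
    "objective",
    "gradients",
    "fit",
    "neighbor_smooth_cold_entities",
    "predict",
]


@dataclass
class LmfConfig:
    r: int = 20
    c: float = 8.0
    lambda_m: float = 0.125
    lambda_d: float = 0.125
    alpha: float = 0.25
    K: int = 5
    learning_rate: float = 0.1
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("latent dimension r must be >= 1")
        if self.c < 1:
            raise ValueError("positive-importance weight c must be >= 1")
        if self.lambda_m <= 0 or self.lambda_d <= 0:
            raise ValueError("L2 weights must be positive")
        if self.alpha < 0:
            raise ValueError("Laplacian weight alpha must be >= 0")
        if self.K < 1:
            raise ValueError("neighborhood size K must be >= 1")
        if self.learning_rate <= 0 or self.max_iter < 1:
            raise ValueError("invalid optimizer settings")


@dataclass
class LatentFactors:
    A: np.ndarray  # n x r microbe factors
    B: np.ndarray  # m x r disease factors

    def __post_init__(self) -> None:
        if self.A.ndim != 2 or self.B.ndim != 2 or self.A.shape[1] != self.B.shape[1]:
            raise ValueError("factor matrices must share the latent dimension")
        if not (np.isfinite(self.A).all() and np.isfinite(self.B).all()):
            raise ValueError("factors must be finite")


def build_laplacian(S: np.ndarray, K: int) -> np.ndarray:
    """Graph Laplacian of the symmetrized K-nearest-neighbor similarity graph.

    Per row, the K largest off-diagonal similarities are kept — concretely,
    entries strictly above the (K+1)-th largest, so a tie spanning the cutoff
    is dropped rather than broken arbitrarily. The kept graph is symmetrized
    as ``(W + W^T) / 2`` and ``L = D - W`` with D the diagonal of row sums.
    L is symmetric PSD with zero row sums.
    """
    S = np.asarray(S, dtype=float)
    k = S.shape[0]
    if S.shape != (k, k):
        raise ValueError("similarity matrix must be square")
    if K >= k:
        raise ValueError(f"K={K} must be smaller than the matrix size {k}")
    off = S.copy().astype(float)
    np.fill_diagonal(off, -np.inf)
    W = np.zeros_like(S)
    for i in range(k):
        cutoff = np.sort(off[i])[::-1][K]  # (K+1)-th largest; -inf when K = k-1
        keep = off[i] > cutoff
        W[i, keep] = S[i, keep]
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    return np.diag(W.sum(axis=1)) - W


def build_weights(
    Y: np.ndarray,
    c: float,
    negative_pairs: list[tuple[int, int]] | None = None,
    excluded: set[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Per-pair training weights: ``c`` on positives; with a negative set, 1 on
    its pairs and 0 elsewhere; without one, 1 on every unlabeled pair.
    ``excluded`` pairs (held-out test entries) always get weight 0.
    """
    Y = np.asarray(Y, dtype=float)
    if negative_pairs is None:
        W = np.ones_like(Y)
    else:
        W = np.zeros_like(Y)
        for i, j in negative_pairs:
            if Y[i, j] != 0:
                raise ValueError(f"negative pair {(i, j)} is a known positive")
            W[i, j] = 1.0
    W[Y == 1] = c
    if excluded:
        for i, j in excluded:
            if Y[i, j] == 0:
                W[i, j] = 0.0
    return W


def _softplus(x: np.ndarray) -> np.ndarray:
    # numerically safe log(1 + exp(x))
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _penalty_matrices(
    SM: np.ndarray, SD: np.ndarray, config: LmfConfig
) -> tuple[np.ndarray, np.ndarray]:
    n, m = SM.shape[0], SD.shape[0]
    Pm = config.lambda_m * np.eye(n)
    Pd = config.lambda_d * np.eye(m)
    if config.alpha > 0:
        Pm = Pm + config.alpha * build_laplacian(SM, min(config.K, n - 1))
        Pd = Pd + config.alpha * build_laplacian(SD, min(config.K, m - 1))
    return Pm, Pd


def objective(
    A: np.ndarray,
    B: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray,
    Pm: np.ndarray,
    Pd: np.ndarray,
) -> float:
    """Weighted logistic loss plus quadratic factor penalties.

    Active pairs (``W > 0``) each contribute
    ``w * (softplus(a_i . b_j) - y_ij * a_i . b_j)`` where ``w`` already folds
    in the c-fold positive weighting; penalties are
    ``0.5 tr(A^T Pm A) + 0.5 tr(B^T Pd B)``.
    """
    X = A @ B.T
    loss = float((W * (_softplus(X) - Y * X)).sum())
    pen = 0.5 * float(np.trace(A.T @ Pm @ A)) + 0.5 * float(np.trace(B.T @ Pd @ B))
    return loss + pen


def gradients(
    A: np.ndarray,
    B: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray,
    Pm: np.ndarray,
    Pd: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`objective` with respect to A and B."""
    X = A @ B.T
    Z = W * (expit(X) - Y)
    return Z @ B + Pm @ A, Z.T @ A + Pd @ B


def fit(
    Y: np.ndarray,
    W: np.ndarray,
    SM: np.ndarray,
    SD: np.ndarray,
    config: LmfConfig | None = None,
    return_trace: bool = False,
) -> LatentFactors | tuple[LatentFactors, list[float]]:
    """Minimize the regularized weighted logistic loss by alternating
    AdaGrad-scaled full-batch gradient descent.

    Factors are initialized i.i.d. Gaussian with standard deviation
    ``1/sqrt(r)`` from the configured seed; the iteration budget is fixed
    (``max_iter`` sweeps over A then B). Raises if the objective becomes
    non-finite.
    """
    config = config or LmfConfig()
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    n, m = Y.shape
    r = min(config.r, n, m)
    if r < config.r:
        logger.info("latent dimension clipped from %d to %d", config.r, r)

    rng = np.random.default_rng(config.seed)
    A = rng.normal(scale=1.0 / np.sqrt(r), size=(n, r))
    B = rng.normal(scale=1.0 / np.sqrt(r), size=(m, r))
    Pm, Pd = _penalty_matrices(SM, SD, config)

    ga = np.zeros_like(A)  # AdaGrad accumulators
    gb = np.zeros_like(B)
    eps = 1e-8
    lr = config.learning_rate

    trace = [objective(A, B, Y, W, Pm, Pd)]
    for it in range(config.max_iter):
        gA, _ = gradients(A, B, Y, W, Pm, Pd)
        ga += gA * gA
        A = A - lr * gA / np.sqrt(ga + eps)

        _, gB = gradients(A, B, Y, W, Pm, Pd)
        gb += gB * gB
        B = B - lr * gB / np.sqrt(gb + eps)

        obj = objective(A, B, Y, W, Pm, Pd)
        if not np.isfinite(obj):
            raise FloatingPointError(f"objective diverged at iteration {it + 1}")
        trace.append(obj)

    factors = LatentFactors(A=A, B=B)
    return (factors, trace) if return_trace else factors


def neighbor_smooth_cold_entities(
    factors: LatentFactors,
    SM: np.ndarray,
    SD: np.ndarray,
    microbe_trained: np.ndarray,
    disease_trained: np.ndarray,
    K: int = 5,
) -> LatentFactors:
    """Replace latent vectors of entities with no training positives by the
    similarity-weighted average of their K most similar trained neighbors.

    Needed to score held-out whole rows/columns: such entities receive no
    likelihood gradient, so their fitted vectors are uninformative. A cold
    entity with no positively-similar trained neighbor keeps its fitted vector
    (with a warning).
    """

    def _smooth(F: np.ndarray, S: np.ndarray, trained: np.ndarray) -> np.ndarray:
        F = F.copy()
        trained = np.asarray(trained, dtype=bool)
        warm = np.flatnonzero(trained)
        if warm.size == 0:
            warnings.warn(
                "no trained entities available for cold-entity smoothing",
                RuntimeWarning,
                stacklevel=3,
            )
            return F
        for i in np.flatnonzero(~trained):
            sims = S[i, warm]
            k = min(K, warm.size)
            nn = warm[np.argsort(sims)[::-1][:k]]
            w = S[i, nn]
            if w.sum() <= 0:
                warnings.warn(
                    f"cold entity {i} has no similar trained neighbors; keeping "
                    "its fitted vector",
                    RuntimeWarning,
                    stacklevel=3,
                )
                continue
            F[i] = (w[:, None] * F[nn]).sum(axis=0) / w.sum()
        return F

    return LatentFactors(
        A=_smooth(factors.A, np.asarray(SM, dtype=float), microbe_trained),
        B=_smooth(factors.B, np.asarray(SD, dtype=float), disease_trained),
    )


def predict(factors: LatentFactors) -> np.ndarray:
    """Association probabilities ``sigmoid(A B^T)``, overflow-safe, in (0, 1)."""
    return expit(factors.A @ factors.B.T)
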