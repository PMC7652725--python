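"""Heterogeneous microbe-disease network: four-block transition matrix and
random walk with restart (RWR) scoring of all pairs.

State ordering throughout is [microbes; diseases], i.e. the first ``n``
coordinates of a walk distribution are microbe nodes and the last ``m`` are
disease nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HeteroTransition",
    "RwrConfig",
    "build_transition",
    "initial_distribution",
    "rwr_solve",
    "score_all_pairs",
]

_MODES = ("disease", "microbe", "average")


@dataclass
class HeteroTransition:
    """Row-stochastic transition blocks over the joint microbe/disease state."""

    H_MM: np.ndarray  # n x n
    H_MD: np.ndarray  # n x m
    H_DM: np.ndarray  # m x n
    H_DD: np.ndarray  # m x m
    lambda_jump: float

    @property
    def n_microbes(self) -> int:
        return self.H_MM.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.H_DD.shape[0]

    def full(self) -> np.ndarray:
        """Assemble the (n+m) x (n+m) transition matrix."""
        top = np.hstack([self.H_MM, self.H_MD])
        bot = np.hstack([self.H_DM, self.H_DD])
        return np.vstack([top, bot])


def build_transition(
    SM: np.ndarray, SD: np.ndarray, Y: np.ndarray, lambda_jump: float = 0.9
) -> HeteroTransition:
    """Derive the four transition-probability blocks from the similarity
    networks and the bipartite association matrix.

    A walker at a microbe with at least one association jumps to one of its
    diseases with total probability ``lambda_jump`` (split proportionally to
    ``Y``) and otherwise moves within the microbe similarity network
    (proportionally to ``SM``); microbes with no associations always stay in
    their similarity network. Disease rows are built symmetrically.
    """
    if not 0.0 <= lambda_jump <= 1.0:
        raise ValueError("lambda_jump must lie in [0, 1]")
    SM = np.asarray(SM, dtype=float)
    SD = np.asarray(SD, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    if SM.shape != (n, n) or SD.shape != (m, m):
        raise ValueError("similarity shapes inconsistent with association matrix")

    sm_rows = SM.sum(axis=1)
    sd_rows = SD.sum(axis=1)
    if (sm_rows <= 0).any() or (sd_rows <= 0).any():
        raise ValueError("similarity rows must have positive sums")

    m_deg = Y.sum(axis=1)  # associations per microbe
    d_deg = Y.sum(axis=0)  # associations per disease

    m_has = m_deg > 0
    d_has = d_deg > 0

    H_MM = SM / sm_rows[:, None]
    H_MM[m_has] *= 1.0 - lambda_jump
    H_MD = np.zeros((n, m))
    H_MD[m_has] = lambda_jump * Y[m_has] / m_deg[m_has, None]

    H_DD = SD / sd_rows[:, None]
    H_DD[d_has] *= 1.0 - lambda_jump
    H_DM = np.zeros((m, n))
    H_DM[d_has] = lambda_jump * Y.T[d_has] / d_deg[d_has, None]

    return HeteroTransition(H_MM, H_MD, H_DM, H_DD, lambda_jump)


@dataclass
class RwrConfig:
    """Settings for the restart walk.

    ``theta`` is the restart probability; ``eta`` splits restart mass between
    the disease node block (weight ``eta``) and the seed microbes (weight
    ``1 - eta``). ``mode`` selects whether pairs are scored from per-disease
    walks, per-microbe walks, or the average of both.
    """

    theta: float = 0.5
    eta: float = 0.9
    tol: float = 1e-11
    max_iter: int = 10_000
    mode: str = "disease"

    def __post_init__(self) -> None:
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")


def initial_distribution(
    query: int, Y_train: np.ndarray, eta: float = 0.9, axis: str = "disease"
) -> np.ndarray:
    """Restart vector of length n+m for a query entity.

    For a disease query: weight ``eta`` on the query disease node and
    ``1 - eta`` spread uniformly over its known microbes. If the query has no
    known partners, the full unit mass sits on the query node. A microbe query
    is handled mirror-wise: weight ``1 - eta`` on the query microbe and ``eta``
    uniform over its known diseases, so ``eta`` always weights the disease
    network.
    """
    Y_train = np.asarray(Y_train, dtype=float)
    n, m = Y_train.shape
    p0 = np.zeros(n + m)
    if axis == "disease":
        seeds = np.flatnonzero(Y_train[:, query] == 1)
        if seeds.size == 0:
            p0[n + query] = 1.0
        else:
            p0[n + query] = eta
            p0[seeds] = (1.0 - eta) / seeds.size
    elif axis == "microbe":
        seeds = np.flatnonzero(Y_train[query] == 1)
        if seeds.size == 0:
            p0[query] = 1.0
        else:
            p0[query] = 1.0 - eta
            p0[n + seeds] = eta / seeds.size
    else:
        raise ValueError("axis must be 'disease' or 'microbe'")
    return p0


def rwr_solve(
    H: HeteroTransition | np.ndarray, p0: np.ndarray, config: RwrConfig | None = None
) -> np.ndarray:
    """Iterate ``P(t+1) = (1 - theta) H^T P(t) + theta P(0)`` to its fixed point.

    ``p0`` may be a single restart vector or a matrix whose columns are restart
    vectors (all columns are iterated jointly; convergence is measured by the
    Frobenius norm of the update). Raises on a non-row-stochastic transition
    matrix; emits a warning if ``max_iter`` is hit before ``tol``.
    """
    config = config or RwrConfig()
    Hm = H.full() if isinstance(H, HeteroTransition) else np.asarray(H, dtype=float)
    if Hm.ndim != 2 or Hm.shape[0] != Hm.shape[1]:
        raise ValueError("transition matrix must be square")
    if not np.allclose(Hm.sum(axis=1), 1.0, atol=1e-8) or (Hm < -1e-12).any():
        raise ValueError("transition matrix is not row-stochastic")

    P0 = np.asarray(p0, dtype=float)
    squeeze = P0.ndim == 1
    if squeeze:
        P0 = P0[:, None]
    if not np.allclose(P0.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("restart vectors must each sum to 1")

    HT = Hm.T
    theta = config.theta
    P = P0.copy()
    for _ in range(config.max_iter):
        P_next = (1.0 - theta) * (HT @ P) + theta * P0
        delta = np.linalg.norm(P_next - P)
        P = P_next
        if delta <= config.tol:
            break
    else:
        warnings.warn(
            f"RWR did not reach tol={config.tol} within {config.max_iter} iterations "
            f"(last update {delta:.3e}); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return P[:, 0] if squeeze else P


def score_all_pairs(
    SM: np.ndarray,
    SD: np.ndarray,
    Y_train: np.ndarray,
    lambda_jump: float = 0.9,
    config: RwrConfig | None = None,
) -> np.ndarray:
    """RWR relevance score for every (microbe, disease) pair.

    Disease mode runs one walk per disease and reads out the microbe block of
    the stationary distribution; microbe mode is the mirror image; average
    mode is the mean of the two score matrices.
    """
    config = config or RwrConfig()
    Y_train = np.asarray(Y_train, dtype=float)
    n, m = Y_train.shape
    H = build_transition(SM, SD, Y_train, lambda_jump)

    def _disease_scores() -> np.ndarray:
        P0 = np.column_stack(
            [initial_distribution(j, Y_train, config.eta, "disease") for j in range(m)]
        )
        P = rwr_solve(H, P0, config)
        return P[:n, :]

    def _microbe_scores() -> np.ndarray:
        P0 = np.column_stack(
            [initial_distribution(i, Y_train, config.eta, "microbe") for i in range(n)]
        )
        P = rwr_solve(H, P0, config)
        return P[n:, :].T

    if config.mode == "disease":
        return _disease_scores()
    if config.mode == "microbe":
        return _microbe_scores()
    return (_disease_scores() + _microbe_scores()) / 2.0
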