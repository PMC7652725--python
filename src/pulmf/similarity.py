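"""Gaussian association-profile (GAP) kernels, symptom cosine similarity,
and the weighted fusion of the two disease similarities.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gap_similarity",
    "symptom_similarity",
    "fuse_disease_similarity",
]


def gap_similarity(profiles: np.ndarray, gamma_prime: float = 1.0) -> np.ndarray:
    """RBF kernel between binary association profiles.

    ``S[i, j] = exp(-g * ||profiles[i] - profiles[j]||^2)`` where the bandwidth
    ``g = gamma_prime / mean_k ||profiles[k]||^2`` is normalized by the average
    squared profile norm. Diagonal is exactly 1; entries lie in (0, 1].

    Parameters
    ----------
    profiles : (k, p) array
        One binary profile per row (rows or columns of the association matrix).
    gamma_prime : float
        Positive bandwidth parameter.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2:
        raise ValueError("profiles must be a 2-D matrix")
    sq_norms = (P * P).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise ValueError("all profiles are zero; kernel bandwidth is undefined")
    g = gamma_prime / mean_sq
    # ||x - y||^2 = ||x||^2 + ||y||^2 - 2 x.y
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    S = np.exp(-g * d2)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2.0


def symptom_similarity(disease_symptom: np.ndarray) -> np.ndarray:
    """Cosine similarity between per-disease symptom weight vectors.

    All-zero rows get similarity 0 to every other disease and 1 to themselves
    (avoids 0/0). Entries lie in [0, 1] for nonnegative input.
    """
    X = np.asarray(disease_symptom, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("disease-symptom matrix must be 2-D with >=1 column")
    if (X < 0).any():
        raise ValueError("symptom weights must be nonnegative")
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = X / safe[:, None]
    S = U @ U.T
    zero = norms == 0
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, 1.0)
    np.clip(S, 0.0, 1.0, out=S)
    return (S + S.T) / 2.0


def fuse_disease_similarity(
    SG: np.ndarray, SS: np.ndarray | None, gamma: float = 0.9
) -> np.ndarray:
    """Weighted sum ``SD = SG + gamma * SS`` of GAP and symptom similarity.

    No renormalization is applied, so fused entries may exceed 1; downstream
    transition-matrix construction row-normalizes anyway. When ``SS`` is
    absent, ``SD = SG``.
    """
    if gamma < 0:
        raise ValueError("fusion weight gamma must be nonnegative")
    SG = np.asarray(SG, dtype=float)
    if SS is None:
        return SG.copy()
    SS = np.asarray(SS, dtype=float)
    if SS.shape != SG.shape:
        raise ValueError("similarity matrices must share shape and label order")
    return SG + gamma * SS
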