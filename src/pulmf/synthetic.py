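"""Planted low-rank logistic generator for association-matrix fixtures.

Emulates the scale and sparsity of curated microbe-disease catalogs
(~300 x ~40 entities, ~4% density) while providing the ground-truth pair
probabilities needed for recovery and enrichment tests. The per-disease
symptom matrix is derived from the same planted disease factors, so symptom
similarity genuinely correlates with latent proximity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_io import AssociationDataset

__all__ = ["SyntheticSpec", "generate", "hmdad_like_preset", "solve_intercept"]


@dataclass
class SyntheticSpec:
    n: int = 100
    m: int = 30
    r_true: int = 4
    density_target: float = 0.05
    symptom_dims: int = 20
    noise_flip: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("need at least one microbe and one disease")
        if not 0.0 < self.density_target < 1.0:
            raise ValueError("density_target must lie in (0, 1)")
        if not 0.0 <= self.noise_flip < 0.5:
            raise ValueError("noise_flip must lie in [0, 0.5)")
        if not 0 <= self.r_true <= min(self.n, self.m):
            raise ValueError("r_true must lie in [0, min(n, m)]")
        if self.symptom_dims < 1:
            raise ValueError("symptom_dims must be >= 1")


def solve_intercept(
    logits: np.ndarray, density_target: float, tol: float = 1e-3
) -> float:
    """Bisection for the intercept b0 with ``mean(sigmoid(logits + b0))`` equal
    to the target density (within ``tol``). Converges for any target in (0, 1)
    because the mean is continuous and strictly increasing in b0."""
    lo, hi = -50.0, 50.0

    def mean_p(b: float) -> float:
        return float(expit(logits + b).mean())

    for _ in range(200):
        mid = (lo + hi) / 2.0
        p = mean_p(mid)
        if abs(p - density_target) <= tol:
            return mid
        if p < density_target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def generate(
    spec: SyntheticSpec,
) -> tuple[AssociationDataset, np.ndarray, np.ndarray]:
    """Draw a synthetic dataset with planted structure.

    Factors U (n x r) and V (m x r) are i.i.d. standard normal; pair
    probabilities are ``p = sigmoid(U V^T + b0)`` with the intercept solved so
    the mean probability hits the density target. Observations are Bernoulli
    draws from p, then each entry is flipped independently with probability
    ``noise_flip``. Symptom weights are ``softplus(V G)`` for a random mixing
    matrix G.

    Returns (dataset, true pair probabilities, disease x symptom matrix).
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.r_true
    U = rng.standard_normal((spec.n, r)) if r else np.zeros((spec.n, 1))
    V = rng.standard_normal((spec.m, r)) if r else np.zeros((spec.m, 1))
    logits = U @ V.T
    b0 = solve_intercept(logits, spec.density_target)
    p_true = expit(logits + b0)

    Y = (rng.random((spec.n, spec.m)) < p_true).astype(float)
    if spec.noise_flip > 0:
        flips = rng.random((spec.n, spec.m)) < spec.noise_flip
        Y = np.where(flips, 1.0 - Y, Y)
    if Y.sum() == 0:  # keep the dataset contract on extreme draws
        i, j = np.unravel_index(int(np.argmax(p_true)), p_true.shape)
        Y[i, j] = 1.0

    G = rng.standard_normal((max(r, 1), spec.symptom_dims))
    symptom = np.logaddexp(0.0, V @ G)  # softplus, strictly positive

    dataset = AssociationDataset(
        microbe_labels=[f"microbe_{i:04d}" for i in range(spec.n)],
        disease_labels=[f"disease_{j:03d}" for j in range(spec.m)],
        Y=Y,
    )
    return dataset, p_true, symptom


def hmdad_like_preset(seed: int = 0) -> SyntheticSpec:
    """A preset at the scale of the curated microbe-disease catalog: 292
    microbes, 39 diseases, ~3.95% density (~450 expected associations)."""
    return SyntheticSpec(
        n=292,
        m=39,
        r_true=4,
        density_target=0.0395,
        symptom_dims=50,
        noise_flip=0.02,
        seed=seed,
    )
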