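"""Spy-based positive-unlabeled selection of reliable negative pairs.

A random subset of known positives (the spies) is relabeled as unknown, the
heterogeneous-network walk is re-scored on the depleted matrix, and the lowest
spy score becomes the reliability threshold: any unlabeled pair scoring below
every planted positive is unlikely to be a missed positive.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .hetnet import RwrConfig, score_all_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "SpyConfig",
    "NegativeSet",
    "reliable_negatives_from_scores",
    "select_reliable_negatives",
    "truncate_to_ratio",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SpyConfig:
    spy_fraction: float = 0.10
    nmdar: float = 1.0
    seed: int = 0
    repeats: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.spy_fraction < 1.0:
            raise ValueError("spy_fraction must lie in (0, 1)")
        if self.nmdar < 0:
            raise ValueError("nmdar (negative:positive ratio) must be >= 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class NegativeSet:
    """Selected reliable-negative pairs with their walk scores, sorted by
    ascending score (most reliable first)."""

    pairs: list[tuple[int, int]]
    scores: np.ndarray
    am_min: float
    fallback: bool = False
    truncated: bool = field(default=False, compare=False)

    def __len__(self) -> int:
        return len(self.pairs)


def reliable_negatives_from_scores(
    AM: np.ndarray,
    Y: np.ndarray,
    spies: list[tuple[int, int]],
    excluded: set[tuple[int, int]] | None = None,
) -> NegativeSet:
    """Threshold step: unlabeled pairs scoring strictly below every spy.

    ``Y`` is the original (spy-complete) association matrix; candidates are
    its zero entries minus any ``excluded`` pairs (e.g. held-out test pairs).
    The returned set is sorted by (score, microbe index, disease index) so
    downstream truncation is deterministic.
    """
    AM = np.asarray(AM, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not spies:
        raise ValueError("need at least one spy to calibrate the threshold")
    excluded = excluded or set()
    am_min = min(AM[i, j] for i, j in spies)

    candidates = [
        (AM[i, j], i, j)
        for i, j in map(tuple, np.argwhere(Y == 0))
        if (i, j) not in excluded
    ]
    below = sorted((s, i, j) for s, i, j in candidates if s < am_min)
    fallback = False
    if not below:
        warnings.warn(
            "no unlabeled pair scored below the spy threshold; falling back to the "
            "lowest-scoring unlabeled pairs overall",
            RuntimeWarning,
            stacklevel=2,
        )
        below = sorted(candidates)
        fallback = True
    return NegativeSet(
        pairs=[(i, j) for _, i, j in below],
        scores=np.array([s for s, _, _ in below]),
        am_min=float(am_min),
        fallback=fallback,
    )


def truncate_to_ratio(rn: NegativeSet, n_positives: int, nmdar: float) -> NegativeSet:
    """Keep the ``round(nmdar * n_positives)`` lowest-scoring pairs.

    If fewer candidates are available, all are kept and a shortfall warning is
    emitted. ``nmdar = 0`` yields an empty set.
    """
    budget = _round_half_up(nmdar * n_positives)
    if budget > len(rn.pairs):
        warnings.warn(
            f"requested {budget} reliable negatives but only {len(rn.pairs)} "
            "candidates are available",
            RuntimeWarning,
            stacklevel=2,
        )
        budget = len(rn.pairs)
    return NegativeSet(
        pairs=rn.pairs[:budget],
        scores=rn.scores[:budget],
        am_min=rn.am_min,
        fallback=rn.fallback,
        truncated=True,
    )


def select_reliable_negatives(
    Y: np.ndarray,
    SM: np.ndarray,
    SD: np.ndarray,
    spy_config: SpyConfig | None = None,
    lambda_jump: float = 0.9,
    rwr_config: RwrConfig | None = None,
    excluded: set[tuple[int, int]] | None = None,
    truncate: bool = True,
) -> NegativeSet:
    """Full spy procedure on an association matrix.

    Per round: sample ``round(spy_fraction * |P|)`` spies (at least 1) from the
    positives, zero them out of ``Y``, score every pair by RWR on the depleted
    heterogeneous network, and record the scores and the minimum spy score.
    With ``repeats > 1`` both are averaged over rounds. The threshold step then
    keeps unlabeled pairs below the (averaged) spy floor, and ``truncate``
    applies the NMDAR budget against the count of original positives.
    """
    spy_config = spy_config or SpyConfig()
    rwr_config = rwr_config or RwrConfig()
    Y = np.asarray(Y, dtype=float)
    positives = [tuple(p) for p in np.argwhere(Y == 1)]
    if len(positives) < 2:
        raise ValueError("need at least 2 positives to run the spy procedure")

    n_spies = max(1, _round_half_up(spy_config.spy_fraction * len(positives)))
    rng = np.random.default_rng(spy_config.seed)

    AM_acc = np.zeros_like(Y)
    am_min_acc = 0.0
    last_spies: list[tuple[int, int]] = []
    for _ in range(spy_config.repeats):
        idx = rng.choice(len(positives), size=n_spies, replace=False)
        spies = [positives[k] for k in sorted(idx)]
        Y_dep = Y.copy()
        for i, j in spies:
            Y_dep[i, j] = 0.0
        AM = score_all_pairs(SM, SD, Y_dep, lambda_jump, rwr_config)
        AM_acc += AM
        am_min_acc += min(AM[i, j] for i, j in spies)
        last_spies = spies

    AM_mean = AM_acc / spy_config.repeats
    am_min = am_min_acc / spy_config.repeats
    # reuse the threshold helper with a synthetic single spy carrying the
    # (averaged) floor score
    i0, j0 = last_spies[0]
    AM_probe = AM_mean.copy()
    AM_probe[i0, j0] = am_min
    rn = reliable_negatives_from_scores(AM_probe, Y, [(i0, j0)], excluded)
    logger.info(
        "spy selection: %d spies, threshold %.3e, %d candidates below threshold%s",
        n_spies,
        am_min,
        len(rn),
        " (fallback)" if rn.fallback else "",
    )
    if truncate:
        rn = truncate_to_ratio(rn, len(positives), spy_config.nmdar)
    return rn
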