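"""Cross-validation harness (mask rows, columns, or entries), rank-based AUC,
and thresholded confusion metrics.

Three masking schemes model three prediction settings: cv1 holds out whole
microbes (new-microbe prediction), cv2 whole diseases, cv3 individual matrix
entries. Everything a fold's model sees — similarities, walk scores, selected
negatives — is recomputed from that fold's training matrix only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
from scipy.stats import rankdata

from .config import RunConfig
from .pipeline import score_matrix_multi

logger = logging.getLogger(__name__)

__all__ = [
    "CvPlan",
    "make_folds",
    "auc",
    "threshold_metrics",
    "run_cv",
    "run_nmdar_sweep",
]

SCHEMES = ("cv1", "cv2", "cv3")


@dataclass
class CvPlan:
    scheme: str = "cv3"
    folds: int = 5
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need >=2 folds and >=1 repeat")


def make_folds(
    Y: np.ndarray, scheme: str, folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, list[tuple[int, int]]]]:
    """Partition one CV repeat into ``folds`` (train matrix, test pairs) splits.

    cv1 partitions microbe rows (a test fold's rows are zeroed in the training
    matrix and *all* pairs in those rows become test pairs, positives and
    negatives alike); cv2 does the same by disease columns; cv3 partitions the
    individual entries.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    rng = np.random.default_rng(seed)
    out: list[tuple[np.ndarray, list[tuple[int, int]]]] = []

    if scheme in ("cv1", "cv2"):
        size = n if scheme == "cv1" else m
        if size < folds:
            raise ValueError(f"{scheme}: only {size} units for {folds} folds")
        units = rng.permutation(size)
        for chunk in np.array_split(units, folds):
            Y_train = Y.copy()
            if scheme == "cv1":
                Y_train[chunk, :] = 0.0
                test = [(int(i), j) for i in chunk for j in range(m)]
            else:
                Y_train[:, chunk] = 0.0
                test = [(i, int(j)) for j in chunk for i in range(n)]
            out.append((Y_train, sorted(test)))
    elif scheme == "cv3":
        if n * m < folds:
            raise ValueError(f"cv3: only {n * m} entries for {folds} folds")
        flat = rng.permutation(n * m)
        for chunk in np.array_split(flat, folds):
            Y_train = Y.copy()
            ii, jj = np.unravel_index(chunk, (n, m))
            Y_train[ii, jj] = 0.0
            out.append((Y_train, sorted(zip(ii.tolist(), jj.tolist()))))
    else:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    return out


def auc(scores: Iterable[float], labels: Iterable[int]) -> float | None:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the probability that a random positive outranks a random negative,
    counting ties as 1/2. Returns None when only one class is present.
    """
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos + n_neg != y.size:
        raise ValueError("labels must be binary")
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def threshold_metrics(
    scores: Iterable[float], labels: Iterable[int], threshold: float = 0.5
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) calling a pair positive when its
    score is >= threshold. A metric with an empty denominator is NaN."""
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels), dtype=float)
    pred = s >= threshold
    tp = float(np.sum(pred & (y == 1)))
    fn = float(np.sum(~pred & (y == 1)))
    tn = float(np.sum(~pred & (y == 0)))
    fp = float(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    acc = (tp + tn) / y.size if y.size else float("nan")
    return sens, spec, acc


def _nan_mean(values: list[float]) -> float | None:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(arr.mean()) if arr.size else None


def run_nmdar_sweep(
    Y: np.ndarray,
    config: RunConfig,
    plan: CvPlan,
    ratios: list[float],
    symptom: np.ndarray | None = None,
    shuffle_similarities: bool = False,
) -> dict[float, dict[str, Any]]:
    """Cross-validate the pipeline at several negative:positive ratios on
    *shared* folds and shared per-fold randomness.

    Returns ``{ratio: report}`` where each report carries per-fold metrics and
    grand means over folds x repeats. Folds whose test set lacks one class have
    undefined AUC and are excluded from the AUC mean (counted in the report).
    """
    Y = np.asarray(Y, dtype=float)
    per_fold: dict[float, list[dict[str, Any]]] = {r: [] for r in ratios}
    n_excluded = 0

    for rep in range(plan.repeats):
        fold_seed = int(np.random.SeedSequence([plan.seed, rep]).generate_state(1)[0])
        for k, (Y_train, test_pairs) in enumerate(
            make_folds(Y, plan.scheme, plan.folds, fold_seed)
        ):
            if Y_train.sum() == 0:
                warnings.warn(
                    f"fold {k} of repeat {rep} has no training positives; skipped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            results, meta = score_matrix_multi(
                Y_train,
                config,
                ratios,
                symptom=symptom,
                excluded=set(test_pairs),
                seed_context=(rep, k),
                shuffle_similarities=shuffle_similarities,
            )
            rows = [p[0] for p in test_pairs]
            cols = [p[1] for p in test_pairs]
            labels = Y[rows, cols]
            for ratio in ratios:
                scores = results[ratio][rows, cols]
                a = auc(scores, labels)
                if a is None:
                    n_excluded += 1
                sens, spec, acc = threshold_metrics(scores, labels, config.threshold)
                per_fold[ratio].append(
                    {
                        "repeat": rep,
                        "fold": k,
                        "auc": a,
                        "sensitivity": sens,
                        "specificity": spec,
                        "accuracy": acc,
                        "n_test": len(test_pairs),
                        "n_test_positives": int(labels.sum()),
                        "cold_entities_smoothed": meta["cold_entities_smoothed"],
                    }
                )

    reports: dict[float, dict[str, Any]] = {}
    for ratio in ratios:
        fold_rows = per_fold[ratio]
        reports[ratio] = {
            "scheme": plan.scheme,
            "folds": plan.folds,
            "repeats": plan.repeats,
            "seed": plan.seed,
            "nmdar": ratio,
            "per_fold": fold_rows,
            "mean": {
                metric: _nan_mean([row[metric] for row in fold_rows])
                for metric in ("auc", "sensitivity", "specificity", "accuracy")
            },
            "n_auc_excluded": n_excluded,
            "config": config.to_dict(),
        }
    return reports


def run_cv(
    Y: np.ndarray,
    config: RunConfig,
    plan: CvPlan,
    symptom: np.ndarray | None = None,
    shuffle_similarities: bool = False,
) -> dict[str, Any]:
    """Cross-validate the full pipeline at the configured NMDAR."""
    return run_nmdar_sweep(
        Y, config, plan, [config.nmdar], symptom, shuffle_similarities
    )[config.nmdar]
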