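"""End-to-end orchestration: association matrix -> similarities -> RWR-guided
negative selection -> regularized logistic matrix factorization -> scores."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Iterable

import numpy as np

from . import __version__
from .config import RunConfig
from .data_io import AssociationDataset, read_association_table, read_matrix, write_ranked_predictions
from .lmf import build_weights, fit, neighbor_smooth_cold_entities, predict
from .pu import NegativeSet, select_reliable_negatives, truncate_to_ratio
from .similarity import fuse_disease_similarity, gap_similarity, symptom_similarity

logger = logging.getLogger(__name__)

__all__ = ["compute_similarities", "score_matrix", "score_matrix_multi", "run_predict"]


def _derived_seed(base: int, *context: int) -> int:
    """Deterministic per-stage seed from the run seed and integer context."""
    return int(np.random.SeedSequence([base, *context]).generate_state(1)[0])


def compute_similarities(
    Y_train: np.ndarray,
    config: RunConfig,
    symptom: np.ndarray | None = None,
    shuffle_seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Microbe and (fused) disease similarity from a training matrix only.

    ``shuffle_seed`` enables a deliberately degenerate control: both similarity
    matrices are permuted by a random relabeling so they no longer correspond
    to the entities they describe (used to measure how much the similarity
    side-information contributes).
    """
    SM = gap_similarity(Y_train, config.gamma_m_prime)
    SG = gap_similarity(Y_train.T, config.gamma_d_prime)
    SS = symptom_similarity(symptom) if symptom is not None else None
    SD = fuse_disease_similarity(SG, SS, config.gamma_fuse)
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        pm = rng.permutation(SM.shape[0])
        pd = rng.permutation(SD.shape[0])
        SM = SM[np.ix_(pm, pm)]
        SD = SD[np.ix_(pd, pd)]
    return SM, SD


def score_matrix_multi(
    Y_train: np.ndarray,
    config: RunConfig,
    ratios: Iterable[float],
    symptom: np.ndarray | None = None,
    excluded: set[tuple[int, int]] | None = None,
    seed_context: tuple[int, ...] = (),
    shuffle_similarities: bool = False,
) -> tuple[dict[float, np.ndarray], dict[str, Any]]:
    """Score every pair once per requested negative:positive ratio.

    The expensive spy/RWR stage is shared across ratios (only the truncation
    budget differs), which keeps ratio sweeps on shared folds cheap and
    guarantees they see identical walk scores. Returns ``{ratio: scores}``
    plus a metadata dict (negative-set provenance, cold-entity counts).
    """
    Y_train = np.asarray(Y_train, dtype=float)
    ratios = list(ratios)
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be >= 0")

    shuffle_seed = (
        _derived_seed(config.seed, 991, *seed_context) if shuffle_similarities else None
    )
    SM, SD = compute_similarities(Y_train, config, symptom, shuffle_seed)

    meta: dict[str, Any] = {
        "rwr_mode": config.rwr_mode,
        "similarities_shuffled": shuffle_similarities,
    }
    rn_full: NegativeSet | None = None
    if any(r > 0 for r in ratios):
        rn_full = select_reliable_negatives(
            Y_train,
            SM,
            SD,
            config.spy_config(seed=_derived_seed(config.seed, 17, *seed_context)),
            config.lambda_jump,
            config.rwr_config(),
            excluded=excluded,
            truncate=False,
        )
        meta["pu_fallback"] = rn_full.fallback
        meta["pu_threshold"] = rn_full.am_min
        meta["pu_candidates"] = len(rn_full)

    n_pos = int(Y_train.sum())
    microbe_trained = Y_train.sum(axis=1) > 0
    disease_trained = Y_train.sum(axis=0) > 0
    n_cold = int((~microbe_trained).sum() + (~disease_trained).sum())
    meta["cold_entities_smoothed"] = n_cold

    lmf_seed = _derived_seed(config.seed, 29, *seed_context)
    results: dict[float, np.ndarray] = {}
    for ratio in ratios:
        if ratio > 0:
            assert rn_full is not None
            rn = truncate_to_ratio(rn_full, n_pos, ratio)
            W = build_weights(Y_train, config.c_weight, rn.pairs, excluded)
            meta.setdefault("negatives_selected", {})[ratio] = len(rn)
        else:
            W = build_weights(Y_train, config.c_weight, None, excluded)
        factors = fit(Y_train, W, SM, SD, config.lmf_config(seed=lmf_seed))
        if n_cold:
            factors = neighbor_smooth_cold_entities(
                factors, SM, SD, microbe_trained, disease_trained, config.knn
            )
        results[ratio] = predict(factors)
    return results, meta


def score_matrix(
    Y_train: np.ndarray,
    config: RunConfig,
    symptom: np.ndarray | None = None,
    excluded: set[tuple[int, int]] | None = None,
    seed_context: tuple[int, ...] = (),
    shuffle_similarities: bool = False,
) -> tuple[np.ndarray, dict[str, Any]]:
    """Full pipeline at the configured NMDAR; returns (scores, metadata)."""
    results, meta = score_matrix_multi(
        Y_train,
        config,
        [config.nmdar],
        symptom,
        excluded,
        seed_context,
        shuffle_similarities,
    )
    return results[config.nmdar], meta


def run_predict(
    association_path: str | Path,
    out_dir: str | Path,
    config: RunConfig,
    symptom_path: str | Path | None = None,
    mask_known: bool = True,
) -> dict[str, Any]:
    """File-level entry point: read inputs, score all pairs, write the ranked
    prediction table and a JSON metadata block. Returns the metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    dataset = read_association_table(association_path)
    symptom = None
    if symptom_path is not None:
        sym = read_matrix(symptom_path)
        # align by label: the pair list may omit diseases the symptom table has
        row_index = {label: k for k, label in enumerate(sym.row_labels)}
        missing = [d for d in dataset.disease_labels if d not in row_index]
        if missing:
            raise ValueError(
                f"symptom matrix lacks rows for diseases: {missing[:5]}"
            )
        symptom = sym.values[[row_index[d] for d in dataset.disease_labels]]

    scores, meta = score_matrix(dataset.Y, config, symptom)
    pred_path = out_dir / "predictions.tsv"
    n_rows = write_ranked_predictions(scores, dataset, pred_path, mask_known=mask_known)

    meta.update(
        {
            "version": __version__,
            "config": config.to_dict(),
            "n_microbes": dataset.n_microbes,
            "n_diseases": dataset.n_diseases,
            "n_positives": int(dataset.Y.sum()),
            "n_duplicates_dropped": dataset.n_duplicates,
            "n_predictions_written": n_rows,
            "mask_known": mask_known,
            "all_unlabeled_negatives_mode": config.nmdar == 0,
        }
    )
    with open(out_dir / "metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %d ranked predictions to %s", n_rows, pred_path)
    return meta
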