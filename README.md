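# pulmf

Microbe–disease association prediction from positives only: a pipeline that
combines Gaussian association-profile similarities, random walk with restart
(RWR) on the joint microbe–disease network, spy-based positive–unlabeled (PU)
selection of reliable negative pairs, and logistic matrix factorization with
K-nearest-neighbor graph-Laplacian regularization.

## Pipeline

1. **similarity** — RBF kernels over the rows/columns of the binary
   association matrix (bandwidth normalized by the mean squared profile norm),
   cosine similarity over an optional disease×symptom table, and a weighted
   fusion of the two disease similarities.
2. **hetnet** — a four-block row-stochastic transition matrix over
   `[microbes; diseases]` (cross-network jump probability λ) and RWR
   (`P(t+1) = (1−θ)Hᵀ P(t) + θ P(0)`) scoring every pair from per-disease or
   per-microbe restarts.
3. **pu** — the spy procedure: a fraction of the known positives is hidden,
   pairs are re-scored by RWR, and unlabeled pairs scoring below every spy are
   kept as reliable negatives, truncated to an `nmdar × |positives|` budget
   (lowest scores first).
4. **lmf** — weighted logistic matrix factorization (positives count `c`-fold)
   over positives ∪ selected negatives (or all unlabeled when `nmdar = 0`),
   with L2 and KNN-Laplacian penalties, solved by alternating AdaGrad descent;
   cold entities (no training positives) get neighbor-smoothed latent vectors.
5. **evaluation** — three five-fold cross-validation schemes (mask microbe
   rows / disease columns / individual entries), rank-based AUC, and
   thresholded sensitivity/specificity/accuracy, with leakage-safe per-fold
   recomputation of every similarity and negative set.
6. **synthetic** — planted low-rank logistic generator (with ground-truth
   pair probabilities) at the scale of curated catalogs for offline testing.

## CLI

```bash
# generate a synthetic dataset (associations.tsv, symptoms.tsv, truth)
pulmf synth --preset hmdad --seed 1 --out data/

# rank all unknown pairs
pulmf predict --associations data/associations.tsv \
    --symptoms data/symptoms.tsv --out run/ --seed 1

# cross-validated metrics (cv1 = new microbes, cv2 = new diseases, cv3 = new pairs)
pulmf run-cv --associations data/associations.tsv --scheme cv3 \
    --folds 5 --repeats 5 --out cv.json

# metrics across negative:positive selection ratios on shared folds
pulmf nmdar-sweep --associations data/associations.tsv --ratios 0,0.5,1,2

# dump the selected reliable negatives
pulmf select-negatives --associations data/associations.tsv --out negatives.tsv
```

All hyperparameters are exposed as flags (`--lambda`, `--theta`, `--eta`,
`--nmdar`, `--rank`, `--c-weight`, `--alpha`, `--knn`, …) and/or a YAML config
via `--config`; precedence is CLI > file > defaults. Defaults follow the
published parameterization (λ=0.9, θ=0.5, η=0.9, c=8, K=5, γ′=1, γ=0.9,
NMDAR=1).

### File formats

- associations: 2+-column TSV of `(microbe, disease)` pairs, `#` comments
  skipped, duplicates collapsed and counted;
- similarity / symptom matrices: labeled TSV (header row + label column);
- predictions: TSV of `(microbe, disease, score, rank)` sorted by descending
  score with deterministic index tie-breaks;
- CV reports: JSON with per-fold metrics, grand means, and a full parameter
  echo including which values were defaulted.

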