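import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import ortho_group

from pulmf.lmf import (
    LatentFactors,
    LmfConfig,
    build_laplacian,
    build_weights,
    fit,
    gradients,
    neighbor_smooth_cold_entities,
    objective,
    predict,
)

from conftest import random_similarity


class TestBuildLaplacian:
    def test_zero_row_sums(self, rng):
        L = build_laplacian(random_similarity(rng, 8), K=3)
        assert np.allclose(L.sum(axis=1), 0.0, atol=1e-12)

    def test_symmetric_psd(self, rng):
        L = build_laplacian(random_similarity(rng, 8), K=3)
        assert np.allclose(L, L.T, atol=1e-12)
        for _ in range(100):
            x = rng.standard_normal(8)
            assert x @ L @ x >= -1e-10

    def test_three_node_chain(self):
        S = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        L = build_laplacian(S, K=1)
        want = np.array([[0.5, -0.5, 0.0], [-0.5, 1.0, -0.5], [0.0, -0.5, 0.5]])
        assert np.allclose(L, want, atol=1e-12)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="K"):
            build_laplacian(np.eye(3), K=3)


class TestBuildWeights:
    def test_positive_weighting(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        W = build_weights(Y, c=8.0)
        assert W[0, 0] == 8.0 and W[1, 1] == 8.0
        assert W[0, 1] == 1.0  # all-unlabeled mode

    def test_negative_set_mode(self):
        Y = np.array([[1.0, 0.0], [0.0, 0.0]])
        W = build_weights(Y, c=8.0, negative_pairs=[(1, 0)])
        assert W[1, 0] == 1.0 and W[0, 1] == 0.0 and W[1, 1] == 0.0

    def test_positive_as_negative_errors(self):
        Y = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="known positive"):
            build_weights(Y, 8.0, negative_pairs=[(0, 0)])

    def test_excluded_pairs_zeroed(self):
        Y = np.array([[1.0, 0.0], [0.0, 0.0]])
        W = build_weights(Y, 8.0, excluded={(0, 1)})
        assert W[0, 1] == 0.0


def _random_problem(rng, n=6, m=4, r=2, c=8.0, alpha=0.25):
    Y = (rng.random((n, m)) < 0.4).astype(float)
    Y[0, 0] = 1.0
    W = build_weights(Y, c)
    SM = random_similarity(rng, n)
    SD = random_similarity(rng, m)
    cfg = LmfConfig(r=r, c=c, alpha=alpha, K=2, seed=int(rng.integers(1 << 30)))
    Pm = cfg.lambda_m * np.eye(n) + cfg.alpha * build_laplacian(SM, cfg.K)
    Pd = cfg.lambda_d * np.eye(m) + cfg.alpha * build_laplacian(SD, cfg.K)
    A = rng.standard_normal((n, r))
    B = rng.standard_normal((m, r))
    return Y, W, SM, SD, cfg, Pm, Pd, A, B


def numeric_gradient(f, X, h=1e-6):
    G = np.zeros_like(X)
    for idx in np.ndindex(X.shape):
        Xp, Xm = X.copy(), X.copy()
        Xp[idx] += h
        Xm[idx] -= h
        G[idx] = (f(Xp) - f(Xm)) / (2 * h)
    return G


class TestObjectiveAndGradients:
    def test_zero_factors_log2_per_active_pair(self, rng):
        Y, W, SM, SD, cfg, Pm, Pd, A, B = _random_problem(rng)
        A0, B0 = np.zeros_like(A), np.zeros_like(B)
        # weighted: each pair contributes w * ln 2 at x = 0
        want = W.sum() * np.log(2.0)
        got = objective(A0, B0, Y, W, np.zeros_like(Pm), np.zeros_like(Pd))
        assert got == pytest.approx(want, rel=1e-12)

    def test_positive_pair_slope_at_zero(self):
        # d/dx [c (ln(1+e^x) - x)] at 0 is c (sigma(0) - 1) = -c/2
        c = 8.0
        Y = np.array([[1.0]])
        W = np.array([[c]])
        f = lambda a: objective(a, np.array([[1.0]]), Y, W, np.zeros((1, 1)), np.zeros((1, 1)))
        slope = (f(np.array([[1e-7]])) - f(np.array([[-1e-7]]))) / 2e-7
        assert slope == pytest.approx(-4.0, abs=1e-5)

    def test_penalties_vanish_at_zero_factors(self, rng):
        Y, W, SM, SD, cfg, Pm, Pd, A, B = _random_problem(rng)
        assert objective(np.zeros_like(A), np.zeros_like(B), Y, W, Pm, Pd) == pytest.approx(
            W.sum() * np.log(2.0), rel=1e-12
        )

    def test_gradients_match_finite_differences(self, rng):
        for _ in range(3):
            Y, W, SM, SD, cfg, Pm, Pd, A, B = _random_problem(rng)
            gA, gB = gradients(A, B, Y, W, Pm, Pd)
            nA = numeric_gradient(lambda X: objective(X, B, Y, W, Pm, Pd), A)
            nB = numeric_gradient(lambda X: objective(A, X, Y, W, Pm, Pd), B)
            assert np.allclose(gA, nA, rtol=1e-5, atol=1e-7)
            assert np.allclose(gB, nB, rtol=1e-5, atol=1e-7)

    def test_rotation_invariance_without_laplacian(self, rng):
        Y, W, SM, SD, cfg, Pm, Pd, A, B = _random_problem(rng, alpha=0.0)
        lam = cfg.lambda_m
        Pm0 = lam * np.eye(A.shape[0])
        Pd0 = cfg.lambda_d * np.eye(B.shape[0])
        Q = ortho_group.rvs(A.shape[1], random_state=0)
        o1 = objective(A, B, Y, W, Pm0, Pd0)
        o2 = objective(A @ Q, B @ Q, Y, W, Pm0, Pd0)
        assert o1 == pytest.approx(o2, rel=1e-10)


class TestFit:
    def test_objective_decreases(self, rng):
        Y, W, SM, SD, cfg, *_ = _random_problem(rng, n=10, m=6, r=3)
        factors, trace = fit(Y, W, SM, SD, cfg, return_trace=True)
        assert trace[-1] <= trace[0]
        assert np.isfinite(trace).all()

    def test_noiseless_low_rank_recovered_on_train(self, rng):
        # strong planted structure, all pairs active, tiny L2: training AUC -> 1
        U = 3.0 * rng.standard_normal((12, 2))
        V = 3.0 * rng.standard_normal((8, 2))
        Y = (U @ V.T > 0).astype(float)
        W = build_weights(Y, c=1.0)
        cfg = LmfConfig(
            r=2, c=1.0, lambda_m=1e-3, lambda_d=1e-3, alpha=0.0, K=2,
            learning_rate=0.3, max_iter=500, seed=0,
        )
        factors = fit(Y, W, np.eye(12), np.eye(8), cfg)
        scores = predict(factors)
        pos = scores[Y == 1]
        neg = scores[Y == 0]
        auc = (pos[:, None] > neg[None, :]).mean()
        assert auc == 1.0

    def test_deterministic_given_seed(self, rng):
        Y, W, SM, SD, cfg, *_ = _random_problem(rng)
        f1 = fit(Y, W, SM, SD, cfg)
        f2 = fit(Y, W, SM, SD, cfg)
        assert np.array_equal(f1.A, f2.A) and np.array_equal(f1.B, f2.B)

    def test_neighborhood_regularization_pulls_twins_together(self, rng):
        # two microbes with identical association rows: higher alpha brings
        # their latent vectors closer at the optimum
        Y = (rng.random((8, 6)) < 0.4).astype(float)
        Y[1] = Y[0]
        Y[0, 0] = Y[1, 0] = 1.0
        from pulmf.similarity import gap_similarity

        SM = gap_similarity(Y)
        SD = gap_similarity(Y.T)
        W = build_weights(Y, c=4.0)
        dists = []
        for alpha in (0.0, 2.0):
            cfg = LmfConfig(r=3, c=4.0, alpha=alpha, K=2, max_iter=300, seed=1)
            f = fit(Y, W, SM, SD, cfg)
            dists.append(np.linalg.norm(f.A[0] - f.A[1]))
        assert dists[1] < dists[0]


class TestNeighborSmoothing:
    def test_identical_neighbors_give_exact_vector(self):
        u = np.array([1.0, 2.0])
        A = np.vstack([u, u, np.zeros(2)])
        B = np.ones((2, 2))
        SM = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.2], [0.3, 0.2, 1.0]])
        out = neighbor_smooth_cold_entities(
            LatentFactors(A=A.copy(), B=B.copy()),
            SM,
            np.eye(2),
            microbe_trained=np.array([True, True, False]),
            disease_trained=np.array([True, True]),
            K=2,
        )
        assert np.allclose(out.A[2], u)

    def test_all_trained_unchanged(self, rng):
        A = rng.standard_normal((4, 2))
        B = rng.standard_normal((3, 2))
        out = neighbor_smooth_cold_entities(
            LatentFactors(A=A.copy(), B=B.copy()),
            random_similarity(rng, 4),
            random_similarity(rng, 3),
            np.ones(4, dtype=bool),
            np.ones(3, dtype=bool),
        )
        assert np.array_equal(out.A, A) and np.array_equal(out.B, B)

    def test_weighted_average(self):
        u1, u2 = np.array([2.0, 0.0]), np.array([0.0, 4.0])
        A = np.vstack([u1, u2, np.zeros(2)])
        SM = np.array([[1.0, 0.0, 3.0], [0.0, 1.0, 1.0], [3.0, 1.0, 1.0]])
        out = neighbor_smooth_cold_entities(
            LatentFactors(A=A.copy(), B=np.ones((2, 2))),
            SM,
            np.eye(2),
            np.array([True, True, False]),
            np.array([True, True]),
            K=2,
        )
        assert np.allclose(out.A[2], 0.75 * u1 + 0.25 * u2)

    def test_no_similar_neighbors_keeps_vector(self):
        A = np.array([[1.0, 1.0], [5.0, 5.0]])
        SM = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.warns(RuntimeWarning, match="no similar trained"):
            out = neighbor_smooth_cold_entities(
                LatentFactors(A=A.copy(), B=np.ones((2, 2))),
                SM,
                np.eye(2),
                np.array([True, False]),
                np.array([True, True]),
                K=1,
            )
        assert np.array_equal(out.A[1], A[1])


class TestPredict:
    def test_zero_logit_is_half(self):
        f = LatentFactors(A=np.zeros((2, 2)), B=np.ones((3, 2)))
        assert np.allclose(predict(f), 0.5)

    def test_saturation_no_overflow(self):
        f = LatentFactors(A=np.array([[1000.0]]), B=np.array([[1.0]]))
        p = predict(f)
        assert p[0, 0] == pytest.approx(1.0)
        assert np.isfinite(p).all()

    def test_ordering_matches_raw_inner_products(self, rng):
        f = LatentFactors(A=rng.standard_normal((5, 3)), B=rng.standard_normal((4, 3)))
        raw = (f.A @ f.B.T).ravel()
        p = predict(f).ravel()
        assert np.array_equal(np.argsort(raw), np.argsort(p))
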