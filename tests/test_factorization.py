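import numpy as np
import pytest

from nmfna import (
    NMF,
    NMFNA,
    ConformabilityError,
    InvalidInputError,
    InvalidParameterError,
    NetNMF,
    SolverConfig,
    TriNMF,
    build_regularizer,
    default_alpha_beta,
    objective_nmfna,
    select_k_svd,
)


def random_networks(seed, m1=40, m2=50, n=20):
    rng = np.random.default_rng(seed)
    X1 = rng.uniform(size=(m1, n))
    X2 = rng.uniform(size=(m2, n))
    R11 = np.abs(np.corrcoef(X1))
    R22 = np.abs(np.corrcoef(X2))
    R12 = np.abs(np.corrcoef(X1, X2)[:m1, m1:])
    return R11, R12, R22


def planted_joint(seed, m1=40, m2=50, k=3, lo=0.2, hi=1.0):
    rng = np.random.default_rng(seed)
    G1 = rng.uniform(lo, hi, size=(m1, k))
    G2 = rng.uniform(lo, hi, size=(m2, k))
    S11 = rng.uniform(lo, hi, size=(k, k)); S11 = (S11 + S11.T) / 2
    S22 = rng.uniform(lo, hi, size=(k, k)); S22 = (S22 + S22.T) / 2
    return G1, G2, S11, S22


class TestDefaults:
    def test_equal_layers_give_unit_weights(self):
        assert default_alpha_beta(10, 10) == (1.0, 1.0)

    def test_cohort_scale_feature_counts(self):
        a, b = default_alpha_beta(21031, 23627)
        assert a == pytest.approx(0.8901, abs=1e-4)
        assert b == pytest.approx(0.7923, abs=1e-4)

    def test_ratio_and_square(self):
        assert default_alpha_beta(2, 1) == (2.0, 4.0)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            default_alpha_beta(0, 5)


class TestSelectK:
    @staticmethod
    def matrix_with_spectrum(s):
        s = np.asarray(s, dtype=float)
        n = len(s)
        rng = np.random.default_rng(0)
        Q1, _ = np.linalg.qr(rng.normal(size=(n, n)))
        Q2, _ = np.linalg.qr(rng.normal(size=(n, n)))
        return Q1 @ np.diag(s) @ Q2

    def test_flattening_spectrum_inflects_at_two(self):
        M = self.matrix_with_spectrum([10, 6, 5.5, 5.4, 5.35])
        assert select_k_svd(M) == 2

    def test_linear_spectrum_falls_back_to_half_rank(self):
        M = self.matrix_with_spectrum(np.arange(10, 0, -1, dtype=float))
        with pytest.warns(RuntimeWarning):
            assert select_k_svd(M) == 5

    def test_low_rank_elbow_detected(self):
        M = self.matrix_with_spectrum([9, 8, 7, 0.01, 0.01, 0.01, 0.01])
        assert select_k_svd(M) == 3

    def test_short_spectrum_rejected(self):
        with pytest.raises(InvalidInputError):
            select_k_svd(np.outer([1.0, 2.0], [1.0, 2.0]))


class TestConfigValidation:
    def test_rank_must_fit_the_matrix(self):
        X = np.random.default_rng(0).uniform(size=(6, 4))
        with pytest.raises(InvalidParameterError):
            NMF(X, k=4)
        with pytest.raises(InvalidParameterError):
            TriNMF(X, k=5)

    def test_negative_data_rejected(self):
        with pytest.raises(InvalidInputError):
            NMF(np.array([[1.0, -0.5], [0.2, 0.3], [0.1, 0.1]]), k=1)

    def test_network_shape_mismatch_rejected(self):
        R11, R12, R22 = random_networks(0)
        with pytest.raises(ConformabilityError):
            NetNMF(R11, R12[:, :-3], R22, k=3)

    def test_laplacian_dimension_mismatch_rejected(self):
        from nmfna import GraphRegularizer

        R11, R12, R22 = random_networks(0)
        bad = GraphRegularizer.zero([str(i) for i in range(R11.shape[0] - 1)])
        with pytest.raises(ConformabilityError):
            NMFNA(R11, R12, R22, k=3, regularizer1=bad)

    def test_bad_config_values_rejected(self):
        for kwargs in ({"k": 0}, {"k": 2, "lambda1": -1}, {"k": 2, "eps": 0},
                       {"k": 2, "s_update": "half"}, {"k": 2, "max_iter": 0}):
            with pytest.raises(InvalidParameterError):
                SolverConfig(**kwargs)


class TestMonotoneDescent:
    """Objective must never increase; spot checks here, the wide sweep in acceptance."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nmf_descends(self, seed):
        X = np.random.default_rng(100 + seed).uniform(size=(40, 20))
        res = NMF(X, k=4, seed=seed).fit()
        assert res.is_monotone(1e-8)
        assert min(F.min() for F in res.factors.values()) >= 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_trinmf_descends(self, seed):
        X = np.random.default_rng(100 + seed).uniform(size=(40, 20))
        res = TriNMF(X, k=4, seed=seed).fit()
        assert res.is_monotone(1e-8)
        assert min(F.min() for F in res.factors.values()) >= 0

    @pytest.mark.parametrize("lam", [0.0, 0.03])
    def test_joint_solver_descends(self, lam):
        R11, R12, R22 = random_networks(7)
        from nmfna import SimilarityNetwork, graph_laplacian, knn_affinity

        net11 = SimilarityNetwork(R11, [str(i) for i in range(40)],
                                  [str(i) for i in range(40)])
        net22 = SimilarityNetwork(R22, [str(i) for i in range(50)],
                                  [str(i) for i in range(50)],
                                  kind="within_layer2")
        reg1 = graph_laplacian(knn_affinity(net11, 5), net11.row_ids)
        reg2 = graph_laplacian(knn_affinity(net22, 5), net22.row_ids)
        res = NMFNA(R11, R12, R22, k=4, regularizer1=reg1, regularizer2=reg2,
                    lambda1=lam, lambda2=lam, seed=3).fit()
        assert res.is_monotone(1e-8)


class TestRecovery:
    def test_rank_one_matrix_recovered_exactly(self):
        rng = np.random.default_rng(7)
        X = np.outer(rng.uniform(0.5, 2, 40), rng.uniform(0.5, 2, 20))
        res = NMF(X, k=1, seed=0, max_iter=500).fit()
        assert res.relative_error() < 1e-3

    def test_zero_matrix_collapses_to_zero_objective(self):
        res = NMF(np.zeros((6, 5)), k=2, seed=0, max_iter=20).fit()
        assert np.all(res.objective_trace == 0.0)

    def test_trinmf_recovers_planted_three_factor_product(self):
        rng = np.random.default_rng(5)
        X = (rng.uniform(0.2, 1, (30, 3)) @ rng.uniform(0.2, 1, (3, 3))
             @ rng.uniform(0.2, 1, (3, 25)))
        res = TriNMF(X, k=3, seed=0, max_iter=3000).fit()
        assert res.relative_error() < 1e-2

    def test_netnmf_recovers_planted_joint_factors(self):
        G1, G2, S11, S22 = planted_joint(2)
        R11, R12, R22 = G1 @ S11 @ G1.T, G1 @ G2.T, G2 @ S22 @ G2.T
        res = NetNMF(R11, R12, R22, k=3, seed=0, max_iter=500).fit()
        assert res.objective < 1e-2 * res.objective_initial


class TestTriNMFSingleStep:
    def test_rank_one_problem_hand_update(self):
        """X=[[4,2],[2,1]] from all-ones factors: one sweep, computed by hand.

        U step: num = X V'S' = (6, 3)', den = U S V V'S' = (2, 2)' -> U = (3, 1.5)'.
        V step (U fresh): num = S'U'X = (15, 7.5), den = S'U'U S V = (11.25, 11.25)
        -> V = (4/3, 2/3).  S step: num = U'X V' = 25, den = U'U S V V' = 25 -> S = 1.
        The sweep lands exactly on X = U S V.
        """
        model = TriNMF(np.array([[4.0, 2.0], [2.0, 1.0]]), k=1, eps=1e-300)
        f = {"U": np.ones((2, 1)), "S": np.ones((1, 1)), "V": np.ones((1, 2))}
        model._update(f)
        assert f["U"][:, 0] == pytest.approx([3.0, 1.5], rel=1e-10)
        assert f["V"][0, :] == pytest.approx([4.0 / 3.0, 2.0 / 3.0], rel=1e-10)
        assert f["S"][0, 0] == pytest.approx(1.0, rel=1e-10)
        assert model._objective(f) == pytest.approx(0.0, abs=1e-12)


class TestReductionAndDeterminism:
    def test_unregularized_limit_reproduces_netnmf_iterations(self):
        R11, R12, R22 = random_networks(21)
        a = NetNMF(R11, R12, R22, k=4, seed=5).fit()
        b = NMFNA(R11, R12, R22, k=4, lambda1=0.0, lambda2=0.0, seed=5).fit()
        assert np.allclose(a.full_trace(), b.full_trace(), rtol=0, atol=0)
        for key in a.factors:
            assert np.array_equal(a.factors[key], b.factors[key])

    def test_identical_seeds_give_bit_identical_traces(self):
        R11, R12, R22 = random_networks(33)
        t1 = NetNMF(R11, R12, R22, k=4, seed=9).fit().full_trace()
        t2 = NetNMF(R11, R12, R22, k=4, seed=9).fit().full_trace()
        assert np.array_equal(t1, t2)


class TestFixedPoint:
    def test_perfect_factors_are_a_fixed_point_without_regularization(self):
        G1, G2, S11, S22 = planted_joint(8)
        R11, R12, R22 = G1 @ S11 @ G1.T, G1 @ G2.T, G2 @ S22 @ G2.T
        model = NMFNA(R11, R12, R22, k=3, lambda1=0.0, lambda2=0.0)
        f = {"G1": G1.copy(), "G2": G2.copy(), "S11": S11.copy(), "S22": S22.copy()}
        model._update(f)
        for name, ref in (("G1", G1), ("G2", G2), ("S11", S11), ("S22", S22)):
            assert np.max(np.abs(f[name] - ref) / ref) < 1e-10


class TestRegularizationEffect:
    def test_smoothness_penalty_decreases_with_stronger_lambda(self, small_networks):
        R11, R12, R22, _ = small_networks
        reg1 = build_regularizer(R11, p=5)
        reg2 = build_regularizer(R22, p=5)
        traces = []
        for lam in (0.0, 0.03, 0.1):
            res = NMFNA(R11, R12, R22, k=3, regularizer1=reg1, regularizer2=reg2,
                        lambda1=lam, lambda2=lam, seed=4).fit()
            G1 = res.factors["G1"]
            traces.append(float(np.trace(G1.T @ reg1.L @ G1)))
        assert traces[0] >= traces[1] >= traces[2]


class TestObjective:
    def test_zero_factors_leave_the_data_norms(self):
        R11, R12, R22 = random_networks(0, m1=10, m2=12, n=20)
        k = 3
        z = objective_nmfna(
            R11, R12, R22, np.zeros((10, 10)), np.zeros((12, 12)),
            np.zeros((10, k)), np.zeros((12, k)), np.zeros((k, k)), np.zeros((k, k)),
            alpha=0.5, beta=0.25,
        )
        expect = (np.linalg.norm(R11) ** 2 + 0.5 * np.linalg.norm(R12) ** 2
                  + 0.25 * np.linalg.norm(R22) ** 2)
        assert z == pytest.approx(expect, rel=1e-12)

    def test_perfect_factors_give_zero(self):
        G1, G2, S11, S22 = planted_joint(1, m1=10, m2=12)
        z = objective_nmfna(
            G1 @ S11 @ G1.T, G1 @ G2.T, G2 @ S22 @ G2.T,
            np.zeros((10, 10)), np.zeros((12, 12)), G1, G2, S11, S22,
        )
        assert z == pytest.approx(0.0, abs=1e-18)

    def test_constant_columns_lie_in_the_laplacian_null_space(self):
        from nmfna import graph_laplacian

        rng = np.random.default_rng(2)
        A = rng.uniform(size=(8, 8))
        Z = (A + A.T) / 2
        np.fill_diagonal(Z, 0.0)
        L = graph_laplacian(Z).L
        G = np.ones((8, 3)) * np.array([1.0, 2.0, 0.5])
        assert np.trace(G.T @ L @ G) == pytest.approx(0.0, abs=1e-10)

    def test_shape_checks(self):
        R11, R12, R22 = random_networks(0, m1=10, m2=12, n=20)
        with pytest.raises(ConformabilityError):
            objective_nmfna(R11, R12.T, R22, np.zeros((10, 10)), np.zeros((12, 12)),
                            np.zeros((10, 2)), np.zeros((12, 2)),
                            np.zeros((2, 2)), np.zeros((2, 2)))


class TestResultsSurface:
    def test_summary_mentions_the_run_vitals(self):
        X = np.random.default_rng(0).uniform(size=(12, 9))
        res = NMF(X, k=2, seed=1, max_iter=50).fit()
        text = res.summary()
        assert "rank k" in text and "final objective" in text and "U: 12x2" in text

    def test_early_stopping_on_relative_change(self):
        rng = np.random.default_rng(4)
        # noisy rank-1 data: the objective plateaus at a positive level
        X = np.outer(np.arange(1.0, 11), np.arange(1.0, 6)) + rng.uniform(0, 0.1, (10, 5))
        res = NMF(X, k=1, seed=0, max_iter=500, tol=1e-8).fit()
        assert res.n_iter < 500
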