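import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmfna import (
    EmptyNetworkError,
    GraphRegularizer,
    InvalidInputError,
    InvalidParameterError,
    build_regularizer,
    cross_network,
    filter_network,
    graph_laplacian,
    knn_affinity,
    pearson_network,
    score_network,
)
from nmfna.exceptions import AlignmentError

from .conftest import make_network, make_omics


class TestPearsonNetwork:
    def test_identical_rows_correlate_perfectly(self):
        X = make_omics([[1, 2, 3, 4], [1, 2, 3, 4], [4, 1, 2, 2]])
        R = pearson_network(X)
        assert R.weights[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(R.weights), 1.0)

    def test_anticorrelated_rows_absolute_valued(self):
        X = make_omics([[1.0, 2, 3], [-1.0, -2, -3]])
        R = pearson_network(X)
        assert R.weights[0, 1] == pytest.approx(1.0)

    def test_signed_mode_drop_zeroes_negative_correlations(self):
        X = make_omics([[1.0, 2, 3], [3.0, 2, 1]])
        R = pearson_network(X, signed_mode="drop")
        assert R.weights[0, 1] == pytest.approx(0.0)

    def test_hand_computed_correlation(self):
        # rows (1,2,3,4) and (2,1,4,3): covariance 3/4·... -> r = 3/5
        X = make_omics([[1, 2, 3, 4], [2, 1, 4, 3]])
        R = pearson_network(X)
        assert R.weights[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            pearson_network(make_omics([[1, 2], [3, 4]]))

    def test_zero_variance_rows_dropped(self, caplog):
        X = make_omics([[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 4, 3]])
        with caplog.at_level("WARNING"):
            R = pearson_network(X)
        assert R.row_ids == ["g0", "g2"]
        assert "zero-variance" in caplog.text

    def test_all_rows_flat_is_an_empty_network(self):
        with pytest.raises(EmptyNetworkError):
            pearson_network(make_omics([[1, 1, 1], [2, 2, 2]]))

    def test_row_affine_rescaling_leaves_network_unchanged(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 12))
        R1 = pearson_network(make_omics(A))
        B = A.copy()
        B[2] = 3.5 * B[2] - 1.25  # positive affine map of one feature row
        R2 = pearson_network(make_omics(B))
        assert np.allclose(R1.weights, R2.weights, atol=1e-12)


class TestCrossNetwork:
    def test_shared_row_gives_unit_similarity(self):
        X1 = make_omics([[1, 2, 3, 4], [5, 1, 2, 2]])
        X2 = make_omics([[1, 2, 3, 4], [9, 2, 4, 4], [0, 1, 0, 1]])
        R = cross_network(X1, X2)
        assert R.shape == (2, 3)
        assert R.weights[0, 0] == pytest.approx(1.0)

    def test_sample_mismatch_names_offenders(self):
        X1 = make_omics([[1, 2, 3]], sample_prefix="a")
        X2 = make_omics([[1, 2, 3]], sample_prefix="b")
        with pytest.raises(AlignmentError, match="a0"):
            cross_network(X1, X2)

    def test_independent_noise_rows_nearly_uncorrelated(self):
        rng = np.random.default_rng(42)
        X1 = make_omics(rng.normal(size=(1, 1000)))
        X2 = make_omics(rng.normal(size=(1, 1000)))
        assert cross_network(X1, X2).weights[0, 0] < 0.1

    def test_cross_agrees_with_within_layer_formula(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(4, 30))
        B = rng.normal(size=(5, 30))
        R = cross_network(make_omics(A), make_omics(B))
        expect = np.abs(np.corrcoef(A, B)[:4, 4:])
        assert np.allclose(R.weights, expect, atol=1e-12)


class TestKnnAffinity:
    def test_three_node_example_keeps_strongest_edges(self):
        R = make_network([[1.0, 0.9, 0.2], [0.9, 1.0, 0.8], [0.2, 0.8, 1.0]])
        Z = knn_affinity(R, p=1)
        assert Z[0, 1] == pytest.approx(0.9)
        assert Z[1, 2] == pytest.approx(0.8)
        assert Z[0, 2] == 0.0

    def test_complete_tie_broken_by_lowest_index(self):
        W = np.full((4, 4), 0.5)
        np.fill_diagonal(W, 1.0)
        Z = knn_affinity(make_network(W), p=1)
        assert np.allclose(Z, Z.T)
        # every row's first pick is its lowest-index neighbour
        assert Z[1, 0] == pytest.approx(0.5)
        assert Z[2, 0] == pytest.approx(0.5)
        assert Z[3, 0] == pytest.approx(0.5)
        assert Z[2, 3] == 0.0

    def test_p_out_of_range_rejected(self):
        R = make_network(np.eye(3))
        with pytest.raises(InvalidParameterError):
            knn_affinity(R, p=3)
        with pytest.raises(InvalidParameterError):
            knn_affinity(R, p=0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), p=st.integers(1, 6))
    def test_symmetry_and_zero_diagonal(self, seed, p):
        rng = np.random.default_rng(seed)
        A = rng.uniform(size=(8, 8))
        W = (A + A.T) / 2
        np.fill_diagonal(W, 1.0)
        Z = knn_affinity(make_network(W), p=p)
        assert np.array_equal(Z, Z.T)
        assert np.all(np.diag(Z) == 0)
        assert np.min(Z) >= 0


class TestGraphLaplacian:
    def test_single_edge(self):
        reg = graph_laplacian([[0, 1], [1, 0]])
        assert np.allclose(reg.D, np.eye(2))
        assert np.allclose(reg.L, [[1, -1], [-1, 1]])

    def test_empty_graph(self):
        reg = graph_laplacian(np.zeros((3, 3)))
        assert np.all(reg.L == 0)

    def test_laplacian_is_positive_semidefinite_with_zero_row_sums(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(size=(10, 10))
        Z = (A + A.T) / 2
        np.fill_diagonal(Z, 0.0)
        reg = graph_laplacian(Z)
        assert np.allclose(reg.L.sum(axis=1), 0.0, atol=1e-12)
        assert np.linalg.eigvalsh(reg.L).min() >= -1e-10

    def test_quadratic_form_identity(self):
        # x' L x = 1/2 sum_ij Z_ij (x_i - x_j)^2
        rng = np.random.default_rng(9)
        A = rng.uniform(size=(10, 10))
        Z = (A + A.T) / 2
        np.fill_diagonal(Z, 0.0)
        reg = graph_laplacian(Z)
        for _ in range(5):
            x = rng.normal(size=10)
            direct = 0.5 * np.sum(Z * (x[:, None] - x[None, :]) ** 2)
            assert x @ reg.L @ x == pytest.approx(direct, rel=1e-10)

    def test_asymmetric_affinity_rejected(self):
        Z = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(InvalidInputError):
            graph_laplacian(Z)

    def test_build_regularizer_chains_knn_and_laplacian(self, small_networks):
        R11, _, _, _ = small_networks
        reg = build_regularizer(R11, p=5)
        assert isinstance(reg, GraphRegularizer)
        assert reg.node_ids == R11.row_ids
        assert np.allclose(np.diag(reg.D), reg.Z.sum(axis=0))


class TestFilterNetwork:
    def test_boundary_edges_removed_at_threshold(self):
        W = np.array([
            [1.00, 0.81, 0.80],
            [0.81, 1.00, 0.79],
            [0.80, 0.79, 1.00],
        ])
        F = filter_network(make_network(W), 0.8)
        assert F.weights[0, 1] == pytest.approx(0.81)
        assert F.weights[0, 2] == 0.0  # equal to the threshold -> removed
        assert F.weights[1, 2] == 0.0
        assert np.all(np.diag(F.weights) == 0)

    def test_zero_threshold_keeps_all_positive_edges(self):
        W = np.array([[1.0, 0.3], [0.3, 1.0]])
        F = filter_network(make_network(W), 0.0)
        assert F.weights[0, 1] == pytest.approx(0.3)

    def test_fully_filtered_network_scores_to_empty_table(self):
        W = np.array([[1.0, 0.2], [0.2, 1.0]])
        F = filter_network(make_network(W), 0.8)
        table = score_network(F)
        assert len(table) == 0

    def test_threshold_must_be_a_proportion(self):
        with pytest.raises(InvalidParameterError):
            filter_network(make_network(np.eye(2)), 1.0)
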