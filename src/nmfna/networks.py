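"""Co-expression network construction and the graph regularizer.

From a pair of omics layers X1 (m1 x n) and X2 (m2 x n) over the same samples,
three networks are built with the Pearson correlation coefficient (PCC):

* ``R11`` — within-layer-1 similarity, |PCC| between layer-1 feature rows;
* ``R22`` — within-layer-2 similarity;
* ``R12`` — rectangular cross-layer similarity between the two feature sets.

Absolute values are taken by default because every matrix entering the
factorization must be non-negative; a strong negative co-expression is still a
strong interaction.  ``signed_mode="drop"`` zeroes negative correlations
instead.

The manifold penalty needs, per layer, a sparse affinity graph Z (symmetrized
p-nearest-neighbour subgraph of the within-layer network, weights carried
over), its diagonal degree matrix D of column sums, and the graph Laplacian
L = D - Z.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np

from .containers import GraphRegularizer, OmicsMatrix, SimilarityNetwork
from .exceptions import (
    EmptyNetworkError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "pearson_network",
    "cross_network",
    "knn_affinity",
    "graph_laplacian",
    "build_regularizer",
    "filter_network",
]

logger = logging.getLogger(__name__)

_SIGNED_MODES = ("absolute", "drop")


def _drop_zero_variance(X: OmicsMatrix) -> OmicsMatrix:
    sd = X.values.std(axis=1)
    keep = sd > 0
    if keep.all():
        return X
    dropped = [f for f, k in zip(X.feature_ids, keep) if not k]
    logger.warning(
        "dropping %d zero-variance feature(s) before correlation: %s%s",
        len(dropped),
        dropped[:5],
        "..." if len(dropped) > 5 else "",
    )
    if not keep.any():
        raise EmptyNetworkError("all features have zero variance; no network to build")
    return OmicsMatrix(
        X.values[keep],
        [f for f, k in zip(X.feature_ids, keep) if k],
        list(X.sample_ids),
    )


def _rectify(R: np.ndarray, signed_mode: str) -> np.ndarray:
    if signed_mode not in _SIGNED_MODES:
        raise InvalidParameterError(f"signed_mode must be one of {_SIGNED_MODES}")
    if signed_mode == "absolute":
        return np.abs(R)
    return np.maximum(R, 0.0)


def pearson_network(
    X: OmicsMatrix, kind: str = "within_layer1", signed_mode: str = "absolute"
) -> SimilarityNetwork:
    """Within-layer co-expression network: |PCC| between feature rows.

    Zero-variance rows are dropped with a logged warning (PCC is undefined for
    them).  Requires at least 3 samples.  The diagonal is 1 (self-correlation).
    """
    if X.n_samples < 3:
        raise InvalidInputError(
            f"need >= 3 samples to estimate correlations, got {X.n_samples}"
        )
    X = _drop_zero_variance(X)
    R = np.corrcoef(X.values)
    R = np.atleast_2d(R)
    R = _rectify(R, signed_mode)
    # numerical safety: clamp round-off, enforce exact symmetry and unit diagonal
    np.clip(R, 0.0, 1.0, out=R)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return SimilarityNetwork(R, list(X.feature_ids), list(X.feature_ids), kind=kind)


def cross_network(
    X1: OmicsMatrix, X2: OmicsMatrix, signed_mode: str = "absolute"
) -> SimilarityNetwork:
    """Rectangular cross-layer network: |PCC| between layer-1 and layer-2 rows."""
    X1.check_samples_aligned(X2)
    if X1.n_samples < 3:
        raise InvalidInputError(
            f"need >= 3 samples to estimate correlations, got {X1.n_samples}"
        )
    X1 = _drop_zero_variance(X1)
    X2 = _drop_zero_variance(X2)

    def _standardize(A: np.ndarray) -> np.ndarray:
        mu = A.mean(axis=1, keepdims=True)
        sd = A.std(axis=1, keepdims=True)
        return (A - mu) / sd

    R = _standardize(X1.values) @ _standardize(X2.values).T / X1.n_samples
    R = _rectify(R, signed_mode)
    np.clip(R, 0.0, 1.0, out=R)
    return SimilarityNetwork(
        R, list(X1.feature_ids), list(X2.feature_ids), kind="cross_layer"
    )


def knn_affinity(R: SimilarityNetwork, p: int = 5) -> np.ndarray:
    """Sparse affinity Z: symmetrized union of each node's p strongest neighbours.

    ``Z[i, j] = R[i, j]`` when j is among the p largest off-diagonal
    similarities of i *or* i is among those of j, else 0.  Ties are broken by
    lowest index (stable sort).  The diagonal is zero.
    """
    if not R.is_within:
        raise InvalidInputError("knn affinity requires a within-layer network")
    m = R.shape[0]
    if not 1 <= p < m:
        raise InvalidParameterError(f"p must satisfy 1 <= p < {m}, got {p}")
    A = R.offdiag()
    Z = np.zeros_like(A)
    # stable argsort on negated weights -> ties resolved toward the lowest index
    order = np.argsort(-A, axis=1, kind="stable")[:, :p]
    rows = np.repeat(np.arange(m), p)
    Z[rows, order.ravel()] = A[rows, order.ravel()]
    Z = np.maximum(Z, Z.T)  # union symmetrization
    np.fill_diagonal(Z, 0.0)
    return Z


def graph_laplacian(Z: np.ndarray, node_ids=None) -> GraphRegularizer:
    """Degree matrix and graph Laplacian L = D - Z of a symmetric affinity matrix."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1]:
        raise InvalidInputError("affinity matrix must be square")
    if not np.allclose(Z, Z.T, atol=1e-12, rtol=0):
        raise InvalidInputError("affinity matrix must be symmetric")
    if np.min(Z) < 0:
        raise InvalidInputError("affinity matrix must be non-negative")
    Z = Z.copy()
    np.fill_diagonal(Z, 0.0)
    D = np.diag(Z.sum(axis=0))
    L = D - Z
    return GraphRegularizer(Z, D, L, list(node_ids) if node_ids is not None else [])


def build_regularizer(R: SimilarityNetwork, p: int = 5) -> GraphRegularizer:
    """Convenience: p-NN affinity of a within-layer network plus its Laplacian."""
    Z = knn_affinity(R, p=p)
    return graph_laplacian(Z, node_ids=R.row_ids)


def filter_network(R: SimilarityNetwork, threshold: float = 0.8) -> SimilarityNetwork:
    """Remove weak edges: weights <= ``threshold`` are zeroed, strictly greater kept.

    The diagonal is zeroed too, since the filtered network feeds graph
    analyses (centralities) where self-loops are meaningless.
    """
    if not 0 <= threshold < 1:
        raise InvalidParameterError(f"threshold must be in [0, 1), got {threshold}")
    W = R.weights.copy()
    W[W <= threshold] = 0.0
    if R.is_within:
        np.fill_diagonal(W, 0.0)
    n_edges = int(np.count_nonzero(np.triu(W, 1))) if R.is_within else int(np.count_nonzero(W))
    logger.info("filter_network(threshold=%g): %d edge(s) retained", threshold, n_edges)
    return SimilarityNetwork(W, list(R.row_ids), list(R.col_ids), kind=R.kind)
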