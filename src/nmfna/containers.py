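"""Core data containers.

The package moves four kinds of objects between stages:

* :class:`OmicsMatrix` — one omics layer, features x samples, e.g. methylation
  beta values or copy-number values over a shared sample cohort;
* :class:`SimilarityNetwork` — a non-negative co-expression network (|Pearson|
  similarities), either within one layer (square, symmetric) or across the two
  layers (rectangular);
* :class:`GraphRegularizer` — the sparse affinity matrix Z, its degree matrix
  D and graph Laplacian L = D - Z used by the manifold penalty;
* :class:`Module` / :class:`ModuleSet` — gene clusters cut from factor-matrix
  columns, each carrying its induced subnetwork.

Containers are thin dataclasses over numpy arrays with identifier bookkeeping
and invariant checks; heavy numerics live in the sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .exceptions import AlignmentError, InvalidInputError

__all__ = [
    "OmicsMatrix",
    "SimilarityNetwork",
    "GraphRegularizer",
    "Module",
    "ModuleSet",
    "PlantedTruth",
]

_SYM_TOL = 1e-12


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})
        raise InvalidInputError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class OmicsMatrix:
    """One omics layer: a features-by-samples value matrix with identifiers."""

    values: np.ndarray
    feature_ids: List[str]
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(i) for i in self.feature_ids]
        self.sample_ids = [str(i) for i in self.sample_ids]
        if self.values.ndim != 2:
            raise InvalidInputError("omics matrix must be 2-D (features x samples)")
        m, n = self.values.shape
        if m != len(self.feature_ids):
            raise InvalidInputError(
                f"{len(self.feature_ids)} feature ids for {m} rows"
            )
        if n != len(self.sample_ids):
            raise InvalidInputError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        _check_unique(self.feature_ids, "feature ids")
        if np.isnan(self.values).any():
            raise InvalidInputError(
                "omics matrix contains missing values; impute or drop before use"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def check_samples_aligned(self, other: "OmicsMatrix") -> None:
        """Raise :class:`AlignmentError` unless both layers share the same samples in order."""
        if self.sample_ids != other.sample_ids:
            off = [
                (a, b)
                for a, b in zip(self.sample_ids, other.sample_ids)
                if a != b
            ]
            extra = abs(len(self.sample_ids) - len(other.sample_ids))
            raise AlignmentError(
                f"sample ids differ between layers: {off[:5]}"
                + (f" (+{extra} length mismatch)" if extra else "")
            )


@dataclass
class SimilarityNetwork:
    """A non-negative similarity (co-expression) network.

    ``kind`` is one of ``within_layer1``, ``within_layer2`` (square, symmetric,
    unit diagonal after self-correlation) or ``cross_layer`` (rectangular).
    """

    weights: np.ndarray
    row_ids: List[str]
    col_ids: List[str]
    kind: str = "within_layer1"

    KINDS = ("within_layer1", "within_layer2", "cross_layer")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.row_ids = [str(i) for i in self.row_ids]
        self.col_ids = [str(i) for i in self.col_ids]
        if self.kind not in self.KINDS:
            raise InvalidInputError(f"unknown network kind {self.kind!r}")
        if self.weights.ndim != 2:
            raise InvalidInputError("network weights must be 2-D")
        r, c = self.weights.shape
        if r != len(self.row_ids) or c != len(self.col_ids):
            raise InvalidInputError("network id lists do not match weight shape")
        if np.min(self.weights) < 0:
            raise InvalidInputError("network weights must be non-negative")
        if self.is_within:
            if r != c:
                raise InvalidInputError("within-layer network must be square")
            if not np.allclose(self.weights, self.weights.T, atol=_SYM_TOL, rtol=0):
                raise InvalidInputError("within-layer network must be symmetric")

    @property
    def is_within(self) -> bool:
        return self.kind != "cross_layer"

    @property
    def shape(self) -> Tuple[int, int]:
        return self.weights.shape

    def offdiag(self) -> np.ndarray:
        """Weights with a zeroed diagonal (for graph analyses; self-loops distort centralities)."""
        W = self.weights.copy()
        if self.is_within:
            np.fill_diagonal(W, 0.0)
        return W

    def induced(self, gene_ids: Sequence[str]) -> "SimilarityNetwork":
        """Submatrix restricted to ``gene_ids`` (within-layer networks only)."""
        if not self.is_within:
            raise InvalidInputError("induced subnetwork requires a within-layer network")
        index = {g: i for i, g in enumerate(self.row_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise AlignmentError(f"genes not in network: {missing[:5]}")
        ids = [g for g in self.row_ids if g in set(gene_ids)]  # preserve network order
        idx = np.array([index[g] for g in ids], dtype=int)
        return SimilarityNetwork(
            self.weights[np.ix_(idx, idx)], ids, list(ids), kind=self.kind
        )


@dataclass
class GraphRegularizer:
    """Affinity/Laplacian pair (Z, D, L) for the manifold penalty Tr(Gᵀ L G)."""

    Z: np.ndarray
    D: np.ndarray
    L: np.ndarray
    node_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        m = self.Z.shape[0]
        if self.Z.shape != (m, m) or self.D.shape != (m, m) or self.L.shape != (m, m):
            raise InvalidInputError("Z, D, L must be square and conformable")
        if not self.node_ids:
            self.node_ids = [str(i) for i in range(m)]

    @property
    def n_nodes(self) -> int:
        return self.Z.shape[0]

    @classmethod
    def zero(cls, node_ids: Sequence[str]) -> "GraphRegularizer":
        """Trivial regularizer (empty affinity graph); turns the penalty off."""
        m = len(node_ids)
        z = np.zeros((m, m))
        return cls(z, z.copy(), z.copy(), list(node_ids))


@dataclass
class Module:
    """A gene cluster from one factor column, with its induced subnetwork."""

    module_id: str
    gene_ids: Set[str]
    layer: str
    column: int
    subnetwork: SimilarityNetwork

    def __post_init__(self) -> None:
        self.gene_ids = set(self.gene_ids)
        if not self.gene_ids:
            raise InvalidInputError(f"module {self.module_id} is empty")

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModuleSet:
    """Modules extracted from one factor matrix (one layer)."""

    modules: List[Module]
    threshold: float = 2.0
    layer: str = ""
    source: str = ""

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def sizes(self) -> List[int]:
        return [m.size for m in self.modules]


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic paired-omics draw.

    ``modules`` maps each layer name to ``{module_id: gene id set}``;
    ``pairings`` lists (layer1 module id, layer2 module id) couples that share
    a latent sample factor; ``params`` records the generation parameters.
    """

    modules: Dict[str, Dict[str, Set[str]]]
    pairings: List[Tuple[str, str]]
    params: Dict[str, float]

    def layer_modules(self, layer: str) -> Dict[str, Set[str]]:
        return self.modules[layer]
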