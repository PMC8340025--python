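import numpy as np
import pytest

from nmfna import (
    Module,
    ModuleSet,
    OmicsMatrix,
    SimilarityNetwork,
    cross_network,
    generate_paired_omics,
    pearson_network,
)


def make_omics(values, feature_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return OmicsMatrix(
        values,
        [f"{feature_prefix}{i}" for i in range(m)],
        [f"{sample_prefix}{j}" for j in range(n)],
    )


def make_network(weights, kind="within_layer1", prefix="g"):
    weights = np.asarray(weights, dtype=float)
    ids = [f"{prefix}{i}" for i in range(weights.shape[0])]
    cols = ids if kind != "cross_layer" else [f"h{j}" for j in range(weights.shape[1])]
    return SimilarityNetwork(weights, ids, cols, kind=kind)


def make_moduleset(gene_sets, layer="within_layer1", threshold=2.0,
                   net_kind="within_layer1"):
    """ModuleSet from bare gene-id sets (trivial identity subnetworks)."""
    modules = []
    for j, genes in enumerate(gene_sets):
        genes = sorted(set(genes))
        sub = SimilarityNetwork(np.eye(len(genes)), genes, list(genes), kind=net_kind)
        modules.append(
            Module(
                module_id=f"{layer}_m{j}",
                gene_ids=set(genes),
                layer=layer,
                column=j,
                subnetwork=sub,
            )
        )
    return ModuleSet(modules=modules, threshold=threshold, layer=layer)


@pytest.fixture(scope="session")
def small_paired():
    """A small planted-module dataset shared across tests (read-only)."""
    return generate_paired_omics(m1=60, m2=70, n=50, k_true=3, rho=0.9,
                                 sigma=0.1, seed=11)


@pytest.fixture(scope="session")
def small_networks(small_paired):
    X1, X2, truth = small_paired
    R11 = pearson_network(X1, kind="within_layer1")
    R22 = pearson_network(X2, kind="within_layer2")
    R12 = cross_network(X1, X2)
    return R11, R12, R22, truth
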