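"""Characteristic-gene ranking by the multimeasure score.

After weak edges are filtered out of a module subnetwork (|PCC| <= 0.8 removed
by default), each surviving gene v is scored by

    MS(v) = DC(v) * BC(v) / EC(v)

combining degree centrality DC (a local feature: number of direct neighbours),
betweenness centrality BC (global: how many shortest paths route through v,
unnormalized, equal-length paths split evenly) and eccentricity EC (global:
the longest shortest-path distance from v within its connected component).
Hubs — high degree, on many shortest paths, close to everything — score
highest; genes at the top of the MS ranking are the module's characteristic
genes.

The filtered graph is treated as an unweighted simple graph by default;
``weighted=True`` uses edge distance 1/weight for the path-based measures and
the weighted degree (strength) for DC.  Isolated nodes have no defined
eccentricity and are excluded from the table (logged).
"""

from __future__ import annotations

import logging
from typing import List

import networkx as nx
import numpy as np
import pandas as pd

from .containers import SimilarityNetwork
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "centralities",
    "multimeasure_score",
    "top_characteristic_genes",
    "score_network",
]

logger = logging.getLogger(__name__)

_COLUMNS = ["gene_id", "DC", "BC", "EC", "MS", "rank"]


def _to_graph(net: SimilarityNetwork) -> nx.Graph:
    if not net.is_within:
        raise InvalidInputError("centralities require a within-layer network")
    W = net.offdiag()
    G = nx.Graph()
    G.add_nodes_from(net.row_ids)
    rows, cols = np.nonzero(np.triu(W, 1))
    for i, j in zip(rows, cols):
        G.add_edge(net.row_ids[i], net.row_ids[j], weight=float(W[i, j]))
    return G


def centralities(net: SimilarityNetwork, weighted: bool = False) -> pd.DataFrame:
    """Degree, betweenness and eccentricity per gene of a filtered network.

    Returns a DataFrame with columns ``gene_id``, ``DC``, ``BC``, ``EC``
    (rows sorted by gene id).  Isolated nodes are excluded.  An empty graph
    yields an empty table.
    """
    G = _to_graph(net)
    isolated = [v for v in G.nodes if G.degree(v) == 0]
    if isolated:
        logger.info(
            "%d isolated node(s) excluded from scoring: %s%s",
            len(isolated), isolated[:5], "..." if len(isolated) > 5 else "",
        )
        G.remove_nodes_from(isolated)
    if G.number_of_nodes() == 0:
        return pd.DataFrame(columns=["gene_id", "DC", "BC", "EC"])

    if weighted:
        for _, _, d in G.edges(data=True):
            d["distance"] = 1.0 / d["weight"]
        dc = dict(G.degree(weight="weight"))
        bc = nx.betweenness_centrality(G, normalized=False, weight="distance")
        ecc = {}
        for comp in nx.connected_components(G):
            sub = G.subgraph(comp)
            ecc.update(nx.eccentricity(sub, weight="distance"))
    else:
        dc = dict(G.degree())
        bc = nx.betweenness_centrality(G, normalized=False)
        ecc = {}
        for comp in nx.connected_components(G):
            ecc.update(nx.eccentricity(G.subgraph(comp)))

    genes = sorted(G.nodes)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "DC": [float(dc[g]) for g in genes],
            "BC": [float(bc[g]) for g in genes],
            "EC": [float(ecc[g]) for g in genes],
        }
    )


def multimeasure_score(table: pd.DataFrame, ec_mode: str = "raw") -> pd.DataFrame:
    """Attach MS = DC * BC / EC and the descending rank (ties by gene id).

    ``ec_mode="reciprocal"`` scores with 1/EC in place of EC, for the reading
    of eccentricity centrality as the reciprocal of the eccentricity.
    """
    if ec_mode not in ("raw", "reciprocal"):
        raise InvalidParameterError("ec_mode must be 'raw' or 'reciprocal'")
    required = {"gene_id", "DC", "BC", "EC"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"table must have columns {sorted(required)}")
    out = table.copy()
    if len(out) == 0:
        out["MS"] = pd.Series(dtype=float)
        out["rank"] = pd.Series(dtype=int)
        return out
    if (out["EC"] <= 0).any():
        raise InvalidInputError("EC must be positive for every scored gene")
    ec = out["EC"] if ec_mode == "raw" else 1.0 / out["EC"]
    out["MS"] = out["DC"] * out["BC"] / ec
    out = out.sort_values(["MS", "gene_id"], ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def top_characteristic_genes(table: pd.DataFrame, n: int) -> List[str]:
    """The first ``n`` gene ids by MS rank; all of them (with a warning) if fewer."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if "rank" not in table.columns:
        raise InvalidInputError("table lacks a rank column; run multimeasure_score first")
    ordered = table.sort_values("rank")["gene_id"].tolist()
    if len(ordered) < n:
        logger.warning("asked for top %d genes but only %d scored", n, len(ordered))
    return ordered[:n]


def score_network(
    net: SimilarityNetwork,
    weighted: bool = False,
    ec_mode: str = "raw",
) -> pd.DataFrame:
    """Convenience: centralities + multimeasure score in one call."""
    return multimeasure_score(centralities(net, weighted=weighted), ec_mode=ec_mode)
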