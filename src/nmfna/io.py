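"""Readers and writers for the package's file formats.

Matrices travel as delimited text: first column feature ids, header row sample
ids, delimiter auto-detected between tab and comma.  Dense networks use the
same layout with ids on both axes.  Networks can also be exported as edge
lists (source, target, weight).  Module sets are written in GMT format
(module id, layer as the description, then the gene ids, tab-separated).
Affinity/Laplacian triples persist in a compressed sparse-matrix container.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    GraphRegularizer,
    Module,
    ModuleSet,
    OmicsMatrix,
    SimilarityNetwork,
)
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_network",
    "write_network",
    "write_edge_list",
    "write_gmt",
    "read_gmt",
    "save_regularizer",
    "load_regularizer",
]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]
_MISSING_POLICIES = ("error", "row_mean")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise InvalidInputError(
        f"{path}: could not detect a tab or comma delimiter in the header"
    )


def _read_table(path: Path) -> pd.DataFrame:
    sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise InvalidInputError(f"{path}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InvalidInputError(f"{path}: duplicate feature ids {dupes[:5]}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        for col in non_numeric:
            bad = df[~df[col].astype(str).str.match(r"^\s*[-+0-9.eE]+\s*$", na=True)]
            if len(bad):
                # +2: header line and 1-based numbering
                line = int(df.index.get_loc(bad.index[0])) + 2
                raise InvalidInputError(
                    f"{path}: non-numeric cell in column {col!r} at line {line}"
                )
        df = df.astype(float)
    return df


def read_matrix(path: PathLike, missing: str = "error") -> OmicsMatrix:
    """Load a feature-by-sample matrix from delimited text.

    ``missing`` selects the policy for NA cells: ``"error"`` (default) rejects
    the file, ``"row_mean"`` imputes each NA with its feature-row mean.
    """
    if missing not in _MISSING_POLICIES:
        raise InvalidParameterError(f"missing policy must be one of {_MISSING_POLICIES}")
    path = Path(path)
    df = _read_table(path)
    if df.isna().any().any():
        if missing == "error":
            n_na = int(df.isna().sum().sum())
            raise InvalidInputError(
                f"{path}: {n_na} missing value(s); rerun with missing='row_mean' to impute"
            )
        logger.warning("%s: imputing %d missing value(s) with row means",
                       path, int(df.isna().sum().sum()))
        df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
    return OmicsMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)),
                       list(df.columns.astype(str)))


def write_matrix(X: OmicsMatrix, path: PathLike, sep: str = "\t") -> None:
    df = pd.DataFrame(X.values, index=X.feature_ids, columns=X.sample_ids)
    df.to_csv(Path(path), sep=sep)


def read_network(path: PathLike, kind: str = "within_layer1") -> SimilarityNetwork:
    """Load a dense network (same delimited layout, ids on both axes)."""
    path = Path(path)
    df = _read_table(path)
    W = df.to_numpy(dtype=float)
    rows, cols = W.shape
    if kind != "cross_layer" and cols > 50 * rows:
        logger.warning(
            "%s: %d columns vs %d rows — this looks like a transposed matrix, "
            "not a within-layer network", path, cols, rows,
        )
    return SimilarityNetwork(W, list(df.index.astype(str)),
                             list(df.columns.astype(str)), kind=kind)


def write_network(net: SimilarityNetwork, path: PathLike, sep: str = "\t") -> None:
    df = pd.DataFrame(net.weights, index=net.row_ids, columns=net.col_ids)
    df.to_csv(Path(path), sep=sep)


def write_edge_list(net: SimilarityNetwork, path: PathLike) -> int:
    """Write nonzero edges as a (source, target, weight) TSV; returns the edge count.

    Within-layer networks emit each undirected edge once (upper triangle,
    diagonal excluded).
    """
    W = net.offdiag() if net.is_within else net.weights
    if net.is_within:
        rows, cols = np.nonzero(np.triu(W, 1))
    else:
        rows, cols = np.nonzero(W)
    with open(Path(path), "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i, j in zip(rows, cols):
            fh.write(f"{net.row_ids[i]}\t{net.col_ids[j]}\t{W[i, j]:.10g}\n")
    return len(rows)


def write_gmt(ms: ModuleSet, path: PathLike) -> None:
    """GMT: one line per module — id, layer (description), then gene ids."""
    with open(Path(path), "w") as fh:
        for mod in ms:
            genes = "\t".join(sorted(mod.gene_ids))
            fh.write(f"{mod.module_id}\t{mod.layer}\t{genes}\n")


def read_gmt(path: PathLike) -> dict:
    """GMT back to a plain {module_id: gene id set} mapping (no subnetworks)."""
    out = {}
    with open(Path(path)) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise InvalidInputError(f"{path}: line {ln}: expected id, description, genes")
            out[parts[0]] = set(parts[2:])
    return out


def save_regularizer(reg: GraphRegularizer, path: PathLike) -> None:
    """Persist Z (sparse) and node ids; D and L are recomputed on load."""
    sp.save_npz(Path(path), sp.csr_matrix(reg.Z))
    ids_path = Path(str(path) + ".ids")
    ids_path.write_text("\n".join(reg.node_ids) + "\n")


def load_regularizer(path: PathLike) -> GraphRegularizer:
    from .networks import graph_laplacian

    Z = sp.load_npz(Path(path)).toarray()
    ids_path = Path(str(path) + ".ids")
    node_ids = ids_path.read_text().splitlines() if ids_path.exists() else None
    return graph_laplacian(Z, node_ids=node_ids)
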