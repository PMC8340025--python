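"""Module extraction from factor matrices, core modules, and the TMS criterion.

A factor matrix G (features x k) localizes k candidate modules: each column is
z-score normalized over the features and the genes whose standardized weight
reaches the threshold (default 2, i.e. two standard deviations above the
column mean) form one module.  A gene may appear in several modules.  The
module with the most genes is the layer's *core module*.

Total module similarity (TMS) between two module sets,

    TMS(A, B) = sum over (x in A, y in B) of |Mx ∩ My| / min(|Mx|, |My|),

quantifies how much two decompositions agree and drives the choice of the
regularization strength lambda: NMFNA is run over a lambda grid and the value
whose modules agree best with a reference decomposition is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import GraphRegularizer, Module, ModuleSet, SimilarityNetwork
from .exceptions import (
    AlignmentError,
    InvalidInputError,
    InvalidParameterError,
    NotFoundError,
)

__all__ = [
    "zscore_columns",
    "extract_modules",
    "core_module",
    "total_module_similarity",
    "select_lambda",
    "LambdaSearchResult",
]

logger = logging.getLogger(__name__)


def zscore_columns(G: np.ndarray) -> np.ndarray:
    """Standardize each column to mean 0, population standard deviation 1.

    Zero-variance columns cannot be standardized and map to all-zero columns
    with a warning (they yield no module downstream).
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise InvalidInputError("factor matrix must be 2-D")
    if G.shape[0] < 2:
        raise InvalidInputError("z-scoring needs at least 2 rows")
    mu = G.mean(axis=0)
    sd = G.std(axis=0)  # population sigma (divide by N)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "%d zero-variance column(s) map to all-zero z-scores: %s",
            int(flat.sum()), np.nonzero(flat)[0].tolist(),
        )
    sd = np.where(flat, 1.0, sd)
    Gz = (G - mu) / sd
    Gz[:, flat] = 0.0
    return Gz


def extract_modules(
    Gz: np.ndarray,
    R: SimilarityNetwork,
    threshold: float = 2.0,
    source: str = "",
) -> ModuleSet:
    """One module per factor column: genes with z-score >= ``threshold``.

    Rows of ``Gz`` must align with ``R``'s gene identifiers.  Columns in which
    no gene reaches the threshold yield no module (logged).  Each module
    carries the induced subnetwork of the layer's within-network.
    """
    Gz = np.asarray(Gz, dtype=float)
    if not R.is_within:
        raise InvalidInputError("modules are cut from a within-layer network")
    if Gz.shape[0] != len(R.row_ids):
        raise AlignmentError(
            f"factor matrix has {Gz.shape[0]} rows but network has "
            f"{len(R.row_ids)} genes"
        )
    layer = R.kind
    ids = np.array(R.row_ids)
    modules: List[Module] = []
    for j in range(Gz.shape[1]):
        members = ids[Gz[:, j] >= threshold]
        if members.size == 0:
            logger.info("column %d yields no gene at z >= %g; skipped", j, threshold)
            continue
        genes = set(members.tolist())
        modules.append(
            Module(
                module_id=f"{layer}_m{j}",
                gene_ids=genes,
                layer=layer,
                column=j,
                subnetwork=R.induced(sorted(genes)),
            )
        )
    return ModuleSet(modules=modules, threshold=threshold, layer=layer, source=source)


def core_module(ms: ModuleSet) -> Module:
    """The module with the most genes; ties go to the lowest column index."""
    if len(ms) == 0:
        raise NotFoundError("module set is empty; no core module")
    best = max(ms.modules, key=lambda m: (m.size, -m.column))
    tied = [m.module_id for m in ms.modules if m.size == best.size]
    if len(tied) > 1:
        logger.info("core-module tie among %s; keeping %s", tied, best.module_id)
    return best


def total_module_similarity(A: ModuleSet, B: ModuleSet) -> float:
    """TMS: sum over all module pairs of |intersection| / min(size)."""
    if len(A) == 0 or len(B) == 0:
        raise InvalidInputError("TMS requires two non-empty module sets")
    total = 0.0
    for ma in A:
        for mb in B:
            inter = len(ma.gene_ids & mb.gene_ids)
            if inter:
                total += inter / min(ma.size, mb.size)
    return total


@dataclass
class LambdaSearchResult:
    """Outcome of the lambda grid search: winning value plus the full TMS curve."""

    best_lambda: float
    curve: pd.DataFrame  # columns: lambda, tms

    def __float__(self) -> float:
        return self.best_lambda


def _tms_or_zero(A: ModuleSet, B: ModuleSet) -> float:
    if len(A) == 0 or len(B) == 0:
        return 0.0
    return total_module_similarity(A, B)


def select_lambda(
    R11: SimilarityNetwork,
    R12: SimilarityNetwork,
    R22: SimilarityNetwork,
    reg1: GraphRegularizer,
    reg2: GraphRegularizer,
    config,
    grid: Sequence[float],
    threshold: float = 2.0,
    mode: str = "baseline",
) -> LambdaSearchResult:
    """Pick the regularization strength from a grid by total module similarity.

    For each grid value, NMFNA is run with ``lambda1 = lambda2 = lambda`` from
    the shared seed and its modules are extracted per layer.  In ``"baseline"``
    mode each run is scored by its TMS against the unregularized (lambda = 0)
    run, summed over the two layers — module stability as the manifold penalty
    is introduced.  ``"consecutive"`` scores each grid point against its
    predecessor instead.  The grid maximum wins; ties go to the smaller lambda.
    """
    from .factorization import NMFNA  # local import to avoid a cycle

    grid = sorted(float(g) for g in grid)
    if not grid:
        raise InvalidParameterError("lambda grid must be non-empty")
    if grid[0] < 0 or grid[-1] > 0.1:
        raise InvalidParameterError("lambda grid must lie within [0, 0.1]")
    if mode not in ("baseline", "consecutive"):
        raise InvalidParameterError("mode must be 'baseline' or 'consecutive'")

    def run(lam: float) -> Tuple[ModuleSet, ModuleSet]:
        model = NMFNA(
            R11, R12, R22, config.k,
            regularizer1=reg1, regularizer2=reg2,
            alpha=config.alpha, beta=config.beta,
            lambda1=lam, lambda2=lam,
            max_iter=config.max_iter, tol=config.tol, seed=config.seed,
            eps=config.eps, s_update=config.s_update,
            strict_g2_update=config.strict_g2_update,
        )
        try:
            res = model.fit()
        except Exception as exc:  # propagate with the offending lambda
            raise InvalidInputError(f"factorization failed at lambda={lam}: {exc}") from exc
        ms1 = extract_modules(zscore_columns(res.factors["G1"]), R11, threshold)
        ms2 = extract_modules(zscore_columns(res.factors["G2"]), R22, threshold)
        return ms1, ms2

    runs = {lam: run(lam) for lam in grid}
    if mode == "baseline":
        base = runs[0.0] if 0.0 in runs else run(0.0)
        refs = {lam: base for lam in grid}
    else:
        refs = {lam: runs[grid[max(0, i - 1)]] for i, lam in enumerate(grid)}

    rows = []
    for lam in grid:
        ms1, ms2 = runs[lam]
        r1, r2 = refs[lam]
        tms = _tms_or_zero(ms1, r1) + _tms_or_zero(ms2, r2)
        rows.append((lam, tms))
        logger.info("lambda=%g -> TMS=%g", lam, tms)
    curve = pd.DataFrame(rows, columns=["lambda", "tms"])
    # grid ascending + argmax taking the first maximum ==> ties resolve to the smaller lambda
    best = float(grid[int(np.argmax(curve["tms"].to_numpy()))])
    return LambdaSearchResult(best_lambda=best, curve=curve)
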