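"""Multiplicative-update solvers: NMF, TriNMF, NetNMF and the graph-regularized NMFNA.

The solvers follow a statsmodels-like layout: a model object is built from the
data matrices plus the structural parameters (rank ``k``, balance weights
``alpha``/``beta``, regularization strengths ``lambda1``/``lambda2``), and its
:meth:`fit` runs the iteration and returns a results object holding the factor
matrices, the per-iteration objective trajectory and a :meth:`summary`.

Objectives
----------
NMF           min ||X - U V||_F^2,                 U >= 0, V >= 0
TriNMF        min ||X - U S V||_F^2,               U, S, V >= 0
NetNMF        min ||R11 - G1 S11 G1'||_F^2 + alpha ||R12 - G1 G2'||_F^2
                  + beta ||R22 - G2 S22 G2'||_F^2
NMFNA         NetNMF objective + lambda1 Tr(G1' L1 G1) + lambda2 Tr(G2' L2 G2)

where R11/R22 are the two within-layer co-expression networks, R12 the
cross-layer network, and L1/L2 graph Laplacians of sparse affinity graphs over
the two feature sets.  The manifold terms pull features that are neighbours in
the affinity graph toward nearby rows of G1/G2, so modules respect the
geometry of the original networks.

All updates are multiplicative: each factor entry is multiplied by a ratio of
non-negative terms, so non-negativity is preserved exactly and the objective
is non-increasing.  With ``lambda1 = lambda2 = 0`` (and empty affinity graphs)
NMFNA performs bit-identical iterations to NetNMF.

Notes on update variants
------------------------
* ``s_update="full"`` (default) applies the S11/S22 multiplicative ratio to
  every entry; ``"diagonal"`` restricts it to the diagonal.  The full update
  is the standard tri-factorization rule and is required for monotone descent.
* For G2, the Laplacian terms enter with the same factor 2 as for G1 by
  default (consistent with the gradient); ``strict_g2_update=True`` drops that
  factor on the G2 side.
* TriNMF's default ``update_rule="ls"`` uses the least-squares tri-factorization
  updates, which are monotone for the stated objective; ``"printed"`` switches
  to the orthogonal-style denominators (U U' X V' S' etc.), which take larger
  steps and may overshoot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .containers import GraphRegularizer, SimilarityNetwork
from .exceptions import (
    ConformabilityError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "SolverConfig",
    "NMF",
    "TriNMF",
    "NetNMF",
    "NMFNA",
    "FactorResults",
    "nmf",
    "trinmf",
    "netnmf",
    "nmfna",
    "objective_nmfna",
    "default_alpha_beta",
    "select_k_svd",
]

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

@dataclass
class SolverConfig:
    """Shared solver configuration.

    Parameters
    ----------
    k : int
        Factor dimension (number of latent modules); must satisfy
        ``k < min(m, n)`` for plain NMF/TriNMF and ``k < min(m1, m2)`` for the
        joint solvers.
    alpha, beta : float
        Balance weights of the cross-layer and layer-2 reconstruction terms.
        ``None`` means use the defaults ``m1/m2`` and ``(m1/m2)**2``.
    lambda1, lambda2 : float
        Graph-regularization strengths (0 disables the manifold penalty).
    max_iter : int
        Number of multiplicative update sweeps (default 200; the objective is
        essentially flat by then at the problem sizes this package targets).
    tol : float
        Optional early-stopping threshold on the relative objective change;
        0 runs all ``max_iter`` iterations.
    seed : int
        Seed of the uniform (0, 1) factor initialization; the only source of
        randomness.
    eps : float
        Guard added to every update denominator to avoid 0/0.
    s_update : str
        ``"full"`` (elementwise on all S entries) or ``"diagonal"``.
    strict_g2_update : bool
        Drop the factor 2 on the Laplacian terms of the G2 update.
    update_rule : str
        TriNMF only: ``"ls"`` or ``"printed"`` (see module docstring).
    """

    k: int = 2
    alpha: Optional[float] = None
    beta: Optional[float] = None
    lambda1: float = 0.0
    lambda2: float = 0.0
    max_iter: int = 200
    tol: float = 0.0
    seed: int = 0
    eps: float = 1e-10
    s_update: str = "full"
    strict_g2_update: bool = False
    update_rule: str = "ls"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidParameterError(f"k must be a positive integer, got {self.k}")
        if self.max_iter < 1:
            raise InvalidParameterError("max_iter must be positive")
        for name in ("lambda1", "lambda2", "tol"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.eps <= 0:
            raise InvalidParameterError("eps must be > 0")
        if self.s_update not in ("full", "diagonal"):
            raise InvalidParameterError("s_update must be 'full' or 'diagonal'")
        if self.update_rule not in ("ls", "printed"):
            raise InvalidParameterError("update_rule must be 'ls' or 'printed'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_alpha_beta(m1: int, m2: int) -> Tuple[float, float]:
    """Default balance weights (m1/m2, (m1/m2)**2) from the two feature counts."""
    if m1 <= 0 or m2 <= 0:
        raise InvalidParameterError("feature counts must be positive")
    r = m1 / m2
    return r, r * r


# --------------------------------------------------------------------------- #
# results
# --------------------------------------------------------------------------- #

class FactorResults:
    """Factors, objective trajectory and diagnostics of one solver run.

    Attributes
    ----------
    factors : dict of str -> ndarray
        Role-tagged factor matrices (``U``/``V``/``S`` or
        ``G1``/``G2``/``S11``/``S22``).
    objective_initial : float
        Objective at the random initialization, before any update.
    objective_trace : ndarray
        Objective after each completed iteration (length = iterations run).
    config : SolverConfig
    """

    def __init__(self, model, factors: Dict[str, np.ndarray],
                 objective_initial: float, objective_trace: np.ndarray,
                 config: SolverConfig):
        self.model = model
        self.factors = factors
        self.objective_initial = float(objective_initial)
        self.objective_trace = np.asarray(objective_trace, dtype=float)
        self.config = config

    def __getattr__(self, name):
        factors = self.__dict__.get("factors", {})
        if name in factors:
            return factors[name]
        raise AttributeError(name)

    @property
    def n_iter(self) -> int:
        return len(self.objective_trace)

    @property
    def objective(self) -> float:
        """Final objective value."""
        return float(self.objective_trace[-1]) if self.n_iter else self.objective_initial

    def full_trace(self) -> np.ndarray:
        """Initial objective followed by the per-iteration trace."""
        return np.concatenate([[self.objective_initial], self.objective_trace])

    def is_monotone(self, rtol: float = 1e-8) -> bool:
        """True when the objective never increases by more than ``rtol`` relative."""
        t = self.full_trace()
        return bool(np.all(t[1:] <= t[:-1] * (1 + rtol)))

    def reconstruction(self) -> Union[np.ndarray, Dict[str, np.ndarray]]:
        return self.model._reconstruction(self.factors)

    def relative_error(self) -> float:
        """Relative Frobenius reconstruction error (joint models: over all blocks)."""
        return self.model._relative_error(self.factors)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} factorization results",
            "=" * 44,
            f"rank k:              {self.config.k}",
            f"iterations:          {self.n_iter}",
            f"initial objective:   {self.objective_initial:.6g}",
            f"final objective:     {self.objective:.6g}",
            f"objective reduction: {1 - self.objective / self.objective_initial:.4%}"
            if self.objective_initial > 0 else "objective reduction: n/a",
            f"relative recon error:{self.relative_error():.4g}",
            f"monotone descent:    {self.is_monotone()}",
            f"seed:                {self.config.seed}",
        ]
        lines.append("factors:")
        for name, F in self.factors.items():
            lines.append(
                f"  {name}: {F.shape[0]}x{F.shape[1]}  min={F.min():.3g} max={F.max():.3g}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<{type(self).__name__} {type(self.model).__name__} k={self.config.k} "
            f"iters={self.n_iter} objective={self.objective:.4g}>"
        )


class JointFactorResults(FactorResults):
    """Results of a joint (NetNMF/NMFNA) run; adds module extraction."""

    def extract_modules(self, threshold: float = 2.0):
        """Cut gene modules from G1/G2 by the z-score >= threshold rule.

        Returns ``(ModuleSet, ModuleSet)`` for layers 1 and 2.  Requires the
        model to have been built from :class:`SimilarityNetwork` inputs (so
        gene identifiers are known).
        """
        from .modules import extract_modules, zscore_columns  # cycle guard

        nets = self.model.networks
        if nets is None:
            raise InvalidInputError(
                "model was built from bare arrays; gene ids unknown — "
                "call modules.extract_modules directly"
            )
        R11, _, R22 = nets
        ms1 = extract_modules(zscore_columns(self.factors["G1"]), R11, threshold)
        ms2 = extract_modules(zscore_columns(self.factors["G2"]), R22, threshold)
        return ms1, ms2


# --------------------------------------------------------------------------- #
# models
# --------------------------------------------------------------------------- #

def _as_array(X, name: str) -> np.ndarray:
    if isinstance(X, SimilarityNetwork):
        X = X.weights
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError(f"{name} must be a 2-D matrix")
    if np.min(X) < 0:
        raise InvalidInputError(f"{name} has negative entries; NMF requires X >= 0")
    return X


class _BaseModel:
    """Common scaffolding: config handling and the fit loop."""

    def __init__(self, **config_kwargs):
        self.config = SolverConfig(**config_kwargs)

    # subclasses define _init_factors / _update / _objective / _reconstruction

    def fit(self, max_iter: Optional[int] = None, tol: Optional[float] = None
            ) -> FactorResults:
        cfg = self.config
        max_iter = cfg.max_iter if max_iter is None else max_iter
        tol = cfg.tol if tol is None else tol
        factors = self._init_factors(cfg.rng())
        obj0 = self._objective(factors)
        trace = []
        prev = obj0
        for it in range(max_iter):
            self._update(factors)
            obj = self._objective(factors)
            trace.append(obj)
            logger.debug("%s iter %d objective %.8g", type(self).__name__, it + 1, obj)
            if tol > 0 and prev > 0 and abs(prev - obj) / prev < tol:
                logger.info(
                    "%s converged after %d iterations (rel change < %g)",
                    type(self).__name__, it + 1, tol,
                )
                break
            prev = obj
        return self._results_cls(self, factors, obj0, np.array(trace), cfg)

    _results_cls = FactorResults

    def _relative_error(self, factors) -> float:
        raise NotImplementedError


class NMF(_BaseModel):
    """Two-factor NMF: X ~ U V with multiplicative updates."""

    def __init__(self, X, k: int, **config_kwargs):
        self.X = _as_array(X, "X")
        m, n = self.X.shape
        if not k < min(m, n):
            raise InvalidParameterError(f"k must satisfy k < min(m, n) = {min(m, n)}")
        super().__init__(k=k, **config_kwargs)

    def _init_factors(self, rng) -> Dict[str, np.ndarray]:
        m, n = self.X.shape
        k = self.config.k
        return {"U": rng.uniform(size=(m, k)), "V": rng.uniform(size=(k, n))}

    def _objective(self, f) -> float:
        return float(np.linalg.norm(self.X - f["U"] @ f["V"]) ** 2)

    def _update(self, f) -> None:
        X, eps = self.X, self.config.eps
        U, V = f["U"], f["V"]
        U *= (X @ V.T) / (U @ V @ V.T + eps)
        V *= (U.T @ X) / (U.T @ U @ V + eps)

    def _reconstruction(self, f) -> np.ndarray:
        return f["U"] @ f["V"]

    def _relative_error(self, f) -> float:
        denom = np.linalg.norm(self.X)
        if denom == 0:
            return 0.0
        return float(np.linalg.norm(self.X - self._reconstruction(f)) / denom)


class TriNMF(_BaseModel):
    """Three-factor NMF: X ~ U S V; S adds a degree of freedom and couples clusters."""

    def __init__(self, X, k: int, **config_kwargs):
        self.X = _as_array(X, "X")
        m, n = self.X.shape
        if not k < min(m, n):
            raise InvalidParameterError(f"k must satisfy k < min(m, n) = {min(m, n)}")
        super().__init__(k=k, **config_kwargs)

    def _init_factors(self, rng) -> Dict[str, np.ndarray]:
        m, n = self.X.shape
        k = self.config.k
        return {
            "U": rng.uniform(size=(m, k)),
            "S": rng.uniform(size=(k, k)),
            "V": rng.uniform(size=(k, n)),
        }

    def _objective(self, f) -> float:
        return float(np.linalg.norm(self.X - f["U"] @ f["S"] @ f["V"]) ** 2)

    def _update(self, f) -> None:
        X, eps = self.X, self.config.eps
        U, S, V = f["U"], f["S"], f["V"]
        if self.config.update_rule == "ls":
            U *= (X @ V.T @ S.T) / (U @ S @ V @ V.T @ S.T + eps)
            V *= (S.T @ U.T @ X) / (S.T @ U.T @ U @ S @ V + eps)
            S *= (U.T @ X @ V.T) / (U.T @ U @ S @ V @ V.T + eps)
        else:  # orthogonal-style denominators
            U *= (X @ V.T @ S.T) / (U @ U.T @ X @ V.T @ S.T + eps)
            V *= (S.T @ U.T @ X) / (S.T @ U.T @ X @ V.T @ V + eps)
            S *= (U.T @ X @ V.T) / (U.T @ U @ S @ V @ V.T + eps)

    def _reconstruction(self, f) -> np.ndarray:
        return f["U"] @ f["S"] @ f["V"]

    def _relative_error(self, f) -> float:
        denom = np.linalg.norm(self.X)
        if denom == 0:
            return 0.0
        return float(np.linalg.norm(self.X - self._reconstruction(f)) / denom)


class NMFNA(_BaseModel):
    """Graph-regularized joint tri-factorization of the three co-expression networks.

    Decomposes R11 ~ G1 S11 G1', R12 ~ G1 G2', R22 ~ G2 S22 G2' with manifold
    penalties lambda_i Tr(Gi' Li Gi).  G1/G2 row patterns locate modules in the
    two layers; the S matrices carry module-module association strengths.
    """

    _results_cls = JointFactorResults

    def __init__(self, R11, R12, R22, k: int,
                 regularizer1: Optional[GraphRegularizer] = None,
                 regularizer2: Optional[GraphRegularizer] = None,
                 **config_kwargs):
        # keep network objects (for ids) when given
        self.networks = None
        if (isinstance(R11, SimilarityNetwork) and isinstance(R22, SimilarityNetwork)
                and isinstance(R12, SimilarityNetwork)):
            self.networks = (R11, R12, R22)
        self.R11 = _as_array(R11, "R11")
        self.R12 = _as_array(R12, "R12")
        self.R22 = _as_array(R22, "R22")
        m1, m1b = self.R11.shape
        m2, m2b = self.R22.shape
        if m1 != m1b or m2 != m2b:
            raise ConformabilityError("R11 and R22 must be square")
        if self.R12.shape != (m1, m2):
            raise ConformabilityError(
                f"R12 must be {m1}x{m2} to match R11/R22, got {self.R12.shape}"
            )
        if not k < min(m1, m2):
            raise InvalidParameterError(
                f"k must satisfy k < min(m1, m2) = {min(m1, m2)}"
            )
        super().__init__(k=k, **config_kwargs)
        cfg = self.config
        if cfg.alpha is None or cfg.beta is None:
            a, b = default_alpha_beta(m1, m2)
            cfg.alpha = a if cfg.alpha is None else cfg.alpha
            cfg.beta = b if cfg.beta is None else cfg.beta
        ids1 = self.networks[0].row_ids if self.networks else [str(i) for i in range(m1)]
        ids2 = self.networks[2].row_ids if self.networks else [str(i) for i in range(m2)]
        self.reg1 = regularizer1 if regularizer1 is not None else GraphRegularizer.zero(ids1)
        self.reg2 = regularizer2 if regularizer2 is not None else GraphRegularizer.zero(ids2)
        if self.reg1.n_nodes != m1:
            raise ConformabilityError(
                f"layer-1 regularizer has {self.reg1.n_nodes} nodes, R11 has {m1}"
            )
        if self.reg2.n_nodes != m2:
            raise ConformabilityError(
                f"layer-2 regularizer has {self.reg2.n_nodes} nodes, R22 has {m2}"
            )

    def _init_factors(self, rng) -> Dict[str, np.ndarray]:
        k = self.config.k
        m1, m2 = self.R11.shape[0], self.R22.shape[0]
        S11 = rng.uniform(size=(k, k))
        S22 = rng.uniform(size=(k, k))
        return {
            "G1": rng.uniform(size=(m1, k)),
            "G2": rng.uniform(size=(m2, k)),
            "S11": (S11 + S11.T) / 2.0,  # symmetric start, symmetric forever
            "S22": (S22 + S22.T) / 2.0,
        }

    def _objective(self, f) -> float:
        cfg = self.config
        return objective_nmfna(
            self.R11, self.R12, self.R22, self.reg1.L, self.reg2.L,
            f["G1"], f["G2"], f["S11"], f["S22"],
            alpha=cfg.alpha, beta=cfg.beta,
            lambda1=cfg.lambda1, lambda2=cfg.lambda2,
        )

    def _update(self, f) -> None:
        cfg = self.config
        eps, a, b = cfg.eps, cfg.alpha, cfg.beta
        l1, l2 = cfg.lambda1, cfg.lambda2
        R11, R12, R22 = self.R11, self.R12, self.R22
        Z1, D1 = self.reg1.Z, self.reg1.D
        Z2, D2 = self.reg2.Z, self.reg2.D
        G1, G2, S11, S22 = f["G1"], f["G2"], f["S11"], f["S22"]

        num = a * (R12 @ G2) + 2.0 * (R11 @ G1 @ S11) + 2.0 * l1 * (Z1 @ G1)
        den = (2.0 * (G1 @ S11 @ (G1.T @ G1) @ S11) + a * (G1 @ (G2.T @ G2))
               + 2.0 * l1 * (D1 @ G1))
        G1 *= num / (den + eps)

        c2 = 1.0 if cfg.strict_g2_update else 2.0
        num = a * (R12.T @ G1) + 2.0 * b * (R22 @ G2 @ S22) + c2 * l2 * (Z2 @ G2)
        den = (2.0 * b * (G2 @ S22 @ (G2.T @ G2) @ S22) + a * (G2 @ (G1.T @ G1))
               + c2 * l2 * (D2 @ G2))
        G2 *= num / (den + eps)

        rat11 = (G1.T @ R11 @ G1) / ((G1.T @ G1) @ S11 @ (G1.T @ G1) + eps)
        rat22 = (G2.T @ R22 @ G2) / ((G2.T @ G2) @ S22 @ (G2.T @ G2) + eps)
        if cfg.s_update == "full":
            S11 *= rat11
            S22 *= rat22
        else:
            d = np.diag_indices(cfg.k)
            S11[d] *= rat11[d]
            S22[d] *= rat22[d]

    def _reconstruction(self, f) -> Dict[str, np.ndarray]:
        return {
            "R11": f["G1"] @ f["S11"] @ f["G1"].T,
            "R12": f["G1"] @ f["G2"].T,
            "R22": f["G2"] @ f["S22"] @ f["G2"].T,
        }

    def _relative_error(self, f) -> float:
        rec = self._reconstruction(f)
        num = (np.linalg.norm(self.R11 - rec["R11"]) ** 2
               + np.linalg.norm(self.R12 - rec["R12"]) ** 2
               + np.linalg.norm(self.R22 - rec["R22"]) ** 2)
        den = (np.linalg.norm(self.R11) ** 2 + np.linalg.norm(self.R12) ** 2
               + np.linalg.norm(self.R22) ** 2)
        if den == 0:
            return 0.0
        return float(np.sqrt(num / den))


class NetNMF(NMFNA):
    """Joint two-layer network factorization without the manifold penalty.

    Identical to :class:`NMFNA` with ``lambda1 = lambda2 = 0`` and empty
    affinity graphs; kept as its own class because it is the natural baseline.
    """

    def __init__(self, R11, R12, R22, k: int, **config_kwargs):
        config_kwargs.pop("lambda1", None)
        config_kwargs.pop("lambda2", None)
        super().__init__(R11, R12, R22, k, lambda1=0.0, lambda2=0.0, **config_kwargs)


# --------------------------------------------------------------------------- #
# functional surface
# --------------------------------------------------------------------------- #

def _cfg_kwargs(config: Optional[SolverConfig]) -> dict:
    if config is None:
        return {}
    d = asdict(config)
    d.pop("k")
    return d


def nmf(X, config: SolverConfig) -> FactorResults:
    """Fit plain NMF with the given configuration."""
    return NMF(X, config.k, **_cfg_kwargs(config)).fit()


def trinmf(X, config: SolverConfig) -> FactorResults:
    """Fit three-factor NMF with the given configuration."""
    return TriNMF(X, config.k, **_cfg_kwargs(config)).fit()


def netnmf(R11, R12, R22, config: SolverConfig) -> JointFactorResults:
    """Fit the unregularized joint network factorization."""
    return NetNMF(R11, R12, R22, config.k, **_cfg_kwargs(config)).fit()


def nmfna(R11, R12, R22, reg1: GraphRegularizer, reg2: GraphRegularizer,
          config: SolverConfig) -> JointFactorResults:
    """Fit the graph-regularized joint network factorization."""
    return NMFNA(
        R11, R12, R22, config.k, regularizer1=reg1, regularizer2=reg2,
        **_cfg_kwargs(config)
    ).fit()


def objective_nmfna(R11, R12, R22, L1, L2, G1, G2, S11, S22,
                    alpha: float = 1.0, beta: float = 1.0,
                    lambda1: float = 0.0, lambda2: float = 0.0) -> float:
    """Scalar objective: three reconstruction terms plus the two manifold penalties."""
    R11, R12, R22 = (np.asarray(A, dtype=float) for A in (R11, R12, R22))
    L1, L2 = np.asarray(L1, dtype=float), np.asarray(L2, dtype=float)
    if R12.shape != (R11.shape[0], R22.shape[0]):
        raise ConformabilityError("R12 shape does not match R11/R22")
    if L1.shape != R11.shape or L2.shape != R22.shape:
        raise ConformabilityError("Laplacian shapes do not match the networks")
    val = float(np.linalg.norm(R11 - G1 @ S11 @ G1.T) ** 2)
    val += alpha * float(np.linalg.norm(R12 - G1 @ G2.T) ** 2)
    val += beta * float(np.linalg.norm(R22 - G2 @ S22 @ G2.T) ** 2)
    val += lambda1 * float(np.trace(G1.T @ L1 @ G1))
    val += lambda2 * float(np.trace(G2.T @ L2 @ G2))
    return val


def select_k_svd(R, min_rank: int = 3, rel_tol: float = 1e-6) -> int:
    """Rank choice: first inflection point of the descending singular-value curve.

    The second difference d2_i = s_{i-1} - 2 s_i + s_{i+1} (1-based i) is
    scanned from i = 2; its sign (with |d2| <= ``rel_tol``·s_1 treated as zero)
    starts at 0, and the first index where the sign differs from the previous
    one is returned.  An exactly linear spectrum has no sign change; the
    fallback then returns floor(rank / 2) with a warning.
    """
    R = np.asarray(R, dtype=float)
    if isinstance(R, np.ndarray) and R.ndim != 2:
        raise InvalidInputError("select_k_svd expects a 2-D matrix")
    s = np.linalg.svd(R, compute_uv=False)
    rank = int(np.sum(s > max(R.shape) * np.finfo(float).eps * s[0])) if s[0] > 0 else 0
    if rank < min_rank:
        raise InvalidInputError(
            f"need >= {min_rank} nonzero singular values, matrix has {rank}"
        )
    tol = rel_tol * s[0]
    prev_sign = 0
    for i in range(1, len(s) - 1):  # 0-based position of 1-based index i+1
        d2 = s[i - 1] - 2.0 * s[i] + s[i + 1]
        sign = 0 if abs(d2) <= tol else (1 if d2 > 0 else -1)
        if sign != prev_sign:
            return i + 1  # 1-based
        prev_sign = sign
    k = rank // 2
    warnings.warn(
        f"singular-value curve has no inflection point; falling back to rank/2 = {k}",
        RuntimeWarning,
        stacklevel=2,
    )
    logger.warning("select_k_svd fallback: no inflection, returning %d", k)
    return k
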