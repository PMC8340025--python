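"""End-to-end pipeline: networks -> factorization -> modules -> gene scores.

Driven by a YAML (or dict) configuration with blocks::

    input:      {layer1: path, layer2: path, missing: error|row_mean}
    # or
    simulate:   {m1, m2, n, k_true, rho, sigma, seed, module_frac}
    network:    {p_neighbors: 5, signed_mode: absolute|drop}
    solver:     {method: nmfna|netnmf|trinmf|nmf, k: int or "svd",
                 alpha, beta, lambda1, lambda2, max_iter, tol, seed,
                 s_update, strict_g2_update, update_rule}
    modules:    {threshold: 2.0}
    scoring:    {pcc_threshold: 0.8, top_n: 10, ec_mode: raw|reciprocal,
                 weighted: false}
    lambda_grid: [0.0, 0.03, 0.1]        # optional TMS-based selection
    output_dir: path

Every stage writes its artifacts under ``output_dir`` and the run closes with
a JSON manifest (config snapshot, input digests, output paths, final
objective) sufficient to re-run the pipeline bit-identically.  A failing stage
aborts with the stage name and leaves a FAILED marker next to the partial
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import yaml

from . import io as nio
from .containers import OmicsMatrix
from .exceptions import InvalidParameterError, PipelineError
from .factorization import (
    NMF,
    NMFNA,
    NetNMF,
    TriNMF,
    select_k_svd,
)
from .modules import (
    core_module,
    extract_modules,
    select_lambda,
    zscore_columns,
)
from .networks import (
    build_regularizer,
    cross_network,
    filter_network,
    pearson_network,
)
from .scoring import score_network, top_characteristic_genes
from .synthetic import generate_paired_omics

__all__ = ["run_pipeline", "RunManifest", "load_config"]

logger = logging.getLogger(__name__)

_METHODS = ("nmf", "trinmf", "netnmf", "nmfna")


@dataclass
class RunManifest:
    """Record of one pipeline run; JSON-serializable."""

    config: dict
    input_digests: Dict[str, str]
    outputs: Dict[str, str]
    final_objective: Optional[float] = None
    n_iterations: Optional[int] = None
    selected_lambda: Optional[float] = None
    selected_k: Optional[int] = None
    package_version: str = ""
    timestamp: str = ""
    status: str = "ok"

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def load_config(source: Union[str, Path, dict]) -> dict:
    if isinstance(source, dict):
        return source
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidParameterError("pipeline config must be a mapping")
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    """Decorator-free helper: wrap stage exceptions with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: Union[str, Path, dict], output_dir: Optional[Union[str, Path]] = None
                 ) -> RunManifest:
    """Execute the full workflow and return the run manifest."""
    from . import __version__

    cfg = load_config(config)
    out_dir = Path(output_dir or cfg.get("output_dir", "nmfna_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    outputs: Dict[str, str] = {}
    digests: Dict[str, str] = {}

    def record(key: str, path: Path) -> Path:
        outputs[key] = str(path)
        return path

    try:
        # ----- inputs ------------------------------------------------------ #
        with _stage("input"):
            if "simulate" in cfg:
                sim = dict(cfg["simulate"])
                X1, X2, truth = generate_paired_omics(**sim)
                nio.write_matrix(X1, record("layer1_matrix", out_dir / "layer1.tsv"))
                nio.write_matrix(X2, record("layer2_matrix", out_dir / "layer2.tsv"))
                truth_path = record("planted_truth", out_dir / "truth.json")
                truth_path.write_text(json.dumps(
                    {
                        "modules": {
                            layer: {k: sorted(v) for k, v in mods.items()}
                            for layer, mods in truth.modules.items()
                        },
                        "pairings": truth.pairings,
                        "params": truth.params,
                    }, indent=2) + "\n")
            elif "input" in cfg:
                inp = cfg["input"]
                missing = inp.get("missing", "error")
                X1 = nio.read_matrix(inp["layer1"], missing=missing)
                X2 = nio.read_matrix(inp["layer2"], missing=missing)
                digests["layer1"] = _digest(Path(inp["layer1"]))
                digests["layer2"] = _digest(Path(inp["layer2"]))
            else:
                raise InvalidParameterError("config needs an 'input' or 'simulate' block")

        # ----- networks ---------------------------------------------------- #
        with _stage("net_construction"):
            ncfg = cfg.get("network", {})
            p = int(ncfg.get("p_neighbors", 5))
            signed = ncfg.get("signed_mode", "absolute")
            R11 = pearson_network(X1, kind="within_layer1", signed_mode=signed)
            R22 = pearson_network(X2, kind="within_layer2", signed_mode=signed)
            R12 = cross_network(X1, X2, signed_mode=signed)
            nio.write_edge_list(R11, record("network_R11", out_dir / "R11_edges.tsv"))
            nio.write_edge_list(R22, record("network_R22", out_dir / "R22_edges.tsv"))
            nio.write_edge_list(R12, record("network_R12", out_dir / "R12_edges.tsv"))
            reg1 = build_regularizer(R11, p=p)
            reg2 = build_regularizer(R22, p=p)
            nio.save_regularizer(reg1, record("regularizer1", out_dir / "reg1.npz"))
            nio.save_regularizer(reg2, record("regularizer2", out_dir / "reg2.npz"))

        # ----- factorization ----------------------------------------------- #
        selected_k = None
        selected_lambda = None
        with _stage("factorization"):
            scfg = dict(cfg.get("solver", {}))
            method = scfg.pop("method", "nmfna").lower()
            if method not in _METHODS:
                raise InvalidParameterError(f"method must be one of {_METHODS}")
            k = scfg.pop("k", None)
            if k in (None, "svd"):
                if k is None and not cfg.get("select_k", False):
                    raise InvalidParameterError(
                        "solver.k is not set: give an integer k, or set solver.k "
                        "to 'svd' (or select_k: true) to choose it from the "
                        "singular-value curve of R11"
                    )
                k = selected_k = int(select_k_svd(R11.weights))
                logger.info("k selected from the singular-value curve: %d", k)
            k = int(k)

            mcfg = cfg.get("modules", {})
            threshold = float(mcfg.get("threshold", 2.0))

            grid = cfg.get("lambda_grid")
            if grid and method == "nmfna":
                from .factorization import SolverConfig

                sel_cfg = SolverConfig(k=k, **{kk: vv for kk, vv in scfg.items()
                                               if kk in SolverConfig.__dataclass_fields__})
                sel = select_lambda(R11, R12, R22, reg1, reg2, sel_cfg, grid,
                                    threshold=threshold)
                selected_lambda = sel.best_lambda
                scfg["lambda1"] = scfg["lambda2"] = selected_lambda
                sel.curve.to_csv(record("tms_curve", out_dir / "tms_curve.csv"),
                                 index=False)

            if method == "nmf":
                model = NMF(R11.weights, k, **scfg)
            elif method == "trinmf":
                model = TriNMF(R11.weights, k, **scfg)
            elif method == "netnmf":
                model = NetNMF(R11, R12, R22, k, **scfg)
            else:
                model = NMFNA(R11, R12, R22, k, regularizer1=reg1,
                              regularizer2=reg2, **scfg)
            results = model.fit()
            np.savetxt(record("objective_trace", out_dir / "objective_trace.tsv"),
                       results.full_trace())
            for name, F in results.factors.items():
                np.savetxt(record(f"factor_{name}", out_dir / f"factor_{name}.tsv"),
                           F, delimiter="\t")
            (out_dir / "summary.txt").write_text(results.summary() + "\n")
            outputs["summary"] = str(out_dir / "summary.txt")

        # ----- modules + scoring ------------------------------------------- #
        score_cfg = cfg.get("scoring", {})
        with _stage("module_detection"):
            if method in ("netnmf", "nmfna"):
                ms1 = extract_modules(zscore_columns(results.factors["G1"]), R11,
                                      threshold, source=method)
                ms2 = extract_modules(zscore_columns(results.factors["G2"]), R22,
                                      threshold, source=method)
            else:
                # single-layer methods factor R11 only
                G = results.factors["U"]
                ms1 = extract_modules(zscore_columns(G), R11, threshold, source=method)
                ms2 = None
            nio.write_gmt(ms1, record("modules_layer1", out_dir / "modules_layer1.gmt"))
            if ms2 is not None:
                nio.write_gmt(ms2, record("modules_layer2", out_dir / "modules_layer2.gmt"))

        with _stage("gene_scoring"):
            pcc_thr = float(score_cfg.get("pcc_threshold", 0.8))
            top_n = int(score_cfg.get("top_n", 10))
            ec_mode = score_cfg.get("ec_mode", "raw")
            weighted = bool(score_cfg.get("weighted", False))
            for label, ms in (("layer1", ms1), ("layer2", ms2)):
                if ms is None or len(ms) == 0:
                    logger.info("no modules for %s; scoring skipped", label)
                    continue
                core = core_module(ms)
                filtered = filter_network(core.subnetwork, pcc_thr)
                table = score_network(filtered, weighted=weighted, ec_mode=ec_mode)
                table.to_csv(record(f"scores_{label}", out_dir / f"scores_{label}.tsv"),
                             sep="\t", index=False)
                top = top_characteristic_genes(table, top_n) if len(table) else []
                (out_dir / f"top_genes_{label}.txt").write_text("\n".join(top) + "\n")
                outputs[f"top_genes_{label}"] = str(out_dir / f"top_genes_{label}.txt")

    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        manifest = RunManifest(
            config=cfg, input_digests=digests, outputs=outputs,
            package_version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"), status="failed",
        )
        manifest.to_json(out_dir / "manifest.json")
        raise

    manifest = RunManifest(
        config=cfg,
        input_digests=digests,
        outputs=outputs,
        final_objective=results.objective,
        n_iterations=results.n_iter,
        selected_lambda=selected_lambda,
        selected_k=selected_k,
        package_version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.to_json(out_dir / "manifest.json")
    outputs["manifest"] = str(out_dir / "manifest.json")
    return manifest
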