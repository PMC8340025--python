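"""Minimal diagnostic plots: objective trajectory and the TMS-vs-lambda curve."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_objective_trace", "plot_tms_curve"]


def plot_objective_trace(results, path: Optional[Union[str, Path]] = None):
    """Objective value per iteration (log scale) for one solver run."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    trace = results.full_trace()
    ax.plot(range(len(trace)), trace, lw=1.5)
    ax.set_yscale("log")
    ax.set_xlabel("iteration")
    ax.set_ylabel("objective")
    ax.set_title(f"{type(results.model).__name__} convergence")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_tms_curve(curve, path: Optional[Union[str, Path]] = None):
    """Total module similarity across the lambda grid."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve["lambda"], curve["tms"], marker="o")
    ax.set_xlabel("lambda")
    ax.set_ylabel("total module similarity")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
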