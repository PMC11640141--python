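"""Diagnostic plots: predicted-versus-observed and centered residual plots."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")  # headless pipeline output
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import residual_diagnostics

__all__ = ["plot_predicted_vs_observed", "plot_residuals"]


def plot_predicted_vs_observed(
    obs, pred, label: str = "", path: Optional[Union[str, Path]] = None
):
    """Scatter of predicted vs observed methane with the line of unity."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(obs, pred, s=18, alpha=0.7, edgecolor="none")
    lim = [0, max(obs.max(), pred.max()) * 1.05]
    ax.plot(lim, lim, "k--", lw=1, label="unity")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel("Observed CH$_4$ (MJ/day)")
    ax.set_ylabel("Predicted CH$_4$ (MJ/day)")
    ax.set_title(label)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_residuals(obs, pred, label: str = "", path: Optional[Union[str, Path]] = None):
    """Residuals (observed - predicted) against mean-centered predictions."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    diag = residual_diagnostics(obs, pred)
    xc = pred - pred.mean()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(xc, obs - pred, s=18, alpha=0.7, edgecolor="none")
    xs = np.linspace(xc.min(), xc.max(), 50)
    ax.plot(xs, diag.intercept + diag.slope * xs, "r-", lw=1.2,
            label=f"bias {diag.intercept:.2f} + {diag.slope:.2f} x")
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("Centered predicted CH$_4$ (MJ/day)")
    ax.set_ylabel("Observed $-$ predicted (MJ/day)")
    ax.set_title(label)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
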