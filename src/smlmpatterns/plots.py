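"""Plotting helpers for PCF / EOM curves and cluster-size distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .clustering import ClusterResult, size_distribution
from .spatial import EOMCurve, PCFResult

__all__ = ["plot_pcf", "plot_eom", "plot_cluster_sizes"]


def plot_pcf(results: dict[str, PCFResult], path: str | None = None, ax=None):
    """Overlay g(r) curves (one per label) with the CSR reference line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for label, res in results.items():
        ax.plot(res.r_centers, res.g, label=label)
    ax.axhline(1.0, color="k", lw=1, label="CSR")
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("g(r)")
    ax.legend(frameon=False, fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_eom(curve: EOMCurve, path: str | None = None, ax=None):
    """EOM(r) with the random-labelling (1) and independence (0) anchors."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    r = curve.r_centers[curve.valid_mask]
    ax.plot(r, curve.eom[curve.valid_mask], color="tab:purple")
    ax.axhline(1.0, color="k", lw=1, ls="--")
    ax.axhline(0.0, color="k", lw=1, ls=":")
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("EOM")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_cluster_sizes(result: ClusterResult, path: str | None = None, ax=None):
    """Cumulative cluster-size distribution."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    dist = size_distribution(result)
    if not dist["degenerate"]:
        ax.step(dist["cumulative_sizes"], dist["cumulative_distribution"], where="post")
    ax.set_xlabel("cluster size")
    ax.set_ylabel("fraction of clusters ≤ size")
    ax.set_ylim(0, 1.05)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
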