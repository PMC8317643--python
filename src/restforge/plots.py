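"""Diagnostic figures: restitution curves, bifurcation diagrams,
dendrograms and inducibility heatmaps.

Plotting is a convenience layer; nothing in the analysis pipeline or the
test suite depends on it.  Each function accepts an optional matplotlib
Axes and returns the Axes it drew on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "plot_restitution",
    "plot_bifurcation",
    "plot_dendrogram",
    "plot_inducibility",
]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_restitution(curve, ax=None, color="C0", label=None):
    """Scatter of (DI, ARI) points with the fitted log curve overlaid."""
    ax = _ax(ax)
    ax.scatter(curve.di, curve.ari, s=10, alpha=0.6, color=color, label=label)
    grid = np.linspace(curve.di.min(), curve.di.max(), 200)
    ax.plot(grid, curve(grid), color=color)
    ax.set_xlabel("DI (ms)")
    ax.set_ylabel("ARI (ms)")
    return ax


def plot_bifurcation(scan, ax=None, color="C0", label=None):
    """Last-two-beat APD pairs against cycle length; onset annotated."""
    ax = _ax(ax)
    ax.plot(scan.cls, scan.apd_pairs[:, 0], ".", ms=3, color=color, label=label)
    ax.plot(scan.cls, scan.apd_pairs[:, 1], ".", ms=3, color=color)
    if scan.onset_cl is not None:
        ax.axvline(scan.onset_cl, ls="--", color=color, alpha=0.6)
    ax.set_xlabel("cycle length (ms)")
    ax.set_ylabel("APD90 (ms)")
    ax.invert_xaxis()
    return ax


def plot_dendrogram(tree, ax=None, **kwargs):
    """Dendrogram of a linkage tree (scipy rendering)."""
    from scipy.cluster.hierarchy import dendrogram

    ax = _ax(ax)
    dendrogram(tree.merges, ax=ax, no_labels=True, **kwargs)
    if tree.cophenetic is not None:
        ax.set_title(f"cophenetic r = {tree.cophenetic:.2f}")
    return ax


def plot_inducibility(imap, ax=None, cmap="Reds"):
    """Sustained-re-entry map over conductivity x coupling interval."""
    ax = _ax(ax)
    ax.pcolormesh(
        imap.sigmas, imap.cis, imap.sustained.T.astype(float), cmap=cmap, shading="nearest"
    )
    ax.set_xlabel("conductivity (S/m)")
    ax.set_ylabel("S1S2 coupling interval (ms)")
    return ax
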