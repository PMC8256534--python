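"""Small matplotlib helpers for the standard figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_correlogram", "plot_pcoa"]


def plot_correlogram(corr: pd.DataFrame, path=None, ax=None):
    """Moran's I against phylogenetic distance with the permutation envelope."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(
        corr["phylo_distance"],
        corr["envelope_low"],
        corr["envelope_high"],
        alpha=0.3,
        color="grey",
        label="95% null envelope",
    )
    ax.plot(corr["phylo_distance"], corr["moran_I"], color="C0", label="Moran's I")
    sig = corr[corr["significant"]]
    if len(sig):
        ax.scatter(sig["phylo_distance"], sig["moran_I"], color="C3", s=12, zorder=3)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("phylogenetic distance")
    ax.set_ylabel("Moran's I")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_pcoa(coordinates: pd.DataFrame, groups: pd.Series | None = None, path=None, ax=None):
    """Scatter of the first two principal coordinates, coloured by group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    x, y = coordinates.iloc[:, 0], coordinates.iloc[:, 1]
    if groups is None:
        ax.scatter(x, y, s=18)
    else:
        groups = groups.loc[coordinates.index]
        for i, (name, idx) in enumerate(groups.groupby(groups).groups.items()):
            ax.scatter(x.loc[idx], y.loc[idx], s=18, label=str(name), color=f"C{i}")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel(coordinates.columns[0])
    ax.set_ylabel(coordinates.columns[1])
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
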