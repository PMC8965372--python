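"""Jaccard heatmap and per-group RoH barplot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_jaccard_heatmap", "plot_roh_fraction_by_group"]


def plot_jaccard_heatmap(jac: pd.DataFrame, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(0.4 * len(jac) + 2, 0.4 * len(jac) + 2))
    im = ax.imshow(jac.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(jac)), jac.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(jac)), jac.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Jaccard coefficient (RoH bp)")
    ax.set_title("RoH colocalization")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_roh_fraction_by_group(inbreeding: pd.DataFrame, metric: str = "F_ROH1",
                               path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = list(pd.unique(inbreeding["group"]))
    med = inbreeding.groupby("group")[metric].median().reindex(groups)
    sd = inbreeding.groupby("group")[metric].std().reindex(groups).fillna(0)
    ax.bar(np.arange(len(groups)), med, yerr=sd, capsize=4)
    ax.set_xticks(np.arange(len(groups)), groups)
    ax.set_ylabel(f"median {metric}")
    ax.set_title("Genome fraction in RoH by group")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
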