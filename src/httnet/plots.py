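"""Optional matplotlib views of experiment outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .comparison import PropagationSummary, ShuffleExperimentTable
from .diversity import BetaMatrix, cluster_order


def plot_shuffle_experiment(table: ShuffleExperimentTable, path) -> None:
    """Mean +/- SD of Mantel r against the number of edge shuffles."""
    agg = table.aggregate()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(agg["n_shuffles"], agg["mean_r"], yerr=agg["sd_r"],
                fmt="o-", capsize=3)
    ax.set_xlabel("edge shuffles")
    ax.set_ylabel("Mantel r vs reference beta matrix")
    ax.set_ylim(-0.1, 1.0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_propagation(summary: PropagationSummary, path) -> None:
    """Box-plots of time-to-x-infected; box width tracks the proportion of
    trajectories that reached x."""
    fp = summary.first_passage
    n = fp.shape[1]
    data, widths, positions = [], [], []
    for x in range(2, n + 1):
        col = fp[:, x - 1]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            continue
        data.append(col)
        widths.append(0.8 * len(col) / fp.shape[0])
        positions.append(x)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.boxplot(data, positions=positions, widths=widths, showfliers=False)
    ax.set_xlabel("species infected")
    ax.set_ylabel("iterations")
    ax.set_title(summary.label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_beta_heatmap(b: BetaMatrix, path, n_blocks: int | None = None) -> None:
    """Beta matrix heatmap with species in dendrogram leaf order."""
    order = cluster_order(b, n_blocks)["order"]
    idx = [b.species_ids.index(s) for s in order]
    vals = b.values[np.ix_(idx, idx)]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(vals, cmap="Greys", vmin=0, vmax=1)
    ax.set_xticks(range(len(order)), order, fontsize=6, rotation=90)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="TE beta-diversity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
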