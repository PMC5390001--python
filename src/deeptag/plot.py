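"""Optional matplotlib figures for clustering and spatial results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from deeptag.clustering import ClusterAssignment


def plot_cluster_profiles(patterns: pd.DataFrame, assignment: ClusterAssignment):
    """One panel per cluster: member profiles (grey) and the centroid (red)."""
    k = assignment.k
    fig, axes = plt.subplots(1, k, figsize=(3 * k, 3), sharey=True)
    axes = np.atleast_1d(axes)
    x = np.arange(patterns.shape[1])
    for j, ax in zip(range(1, k + 1), axes):
        members = patterns.loc[assignment.labels[assignment.labels == j].index]
        for _, row in members.iterrows():
            ax.plot(x, row.to_numpy(), color="0.7", lw=0.5)
        ax.plot(x, assignment.centroids.loc[j].to_numpy(), color="crimson", lw=2)
        ax.set_title(f"cluster {j} (n={len(members)})")
        ax.set_xticks(x, patterns.columns, rotation=45, fontsize=7)
    axes[0].set_ylabel("standardized group mean")
    fig.tight_layout()
    return fig


def plot_coexpression_ecdf(ecdf_data: pd.DataFrame):
    """Cumulative distributions of gene-set pair similarities vs null means."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    for which, group in ecdf_data.groupby("which"):
        vals = np.sort(group["value"].to_numpy())
        ax.step(vals, np.arange(1, len(vals) + 1) / len(vals), where="post", label=which)
    ax.set_xlabel("cosine similarity")
    ax.set_ylabel("CDF")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
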