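"""Optional figure output (SVG): loading bar charts and cosine heatmaps."""

from __future__ import annotations

import numpy as np

from .comparison import ComparisonReport
from .decomposition import CrossFit

__all__ = ["plot_brain_loadings", "plot_cosine_heatmap"]


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_brain_loadings(fit: CrossFit, path, component: int = 0) -> None:
    """Horizontal bar chart of one component's brain structure coefficients."""
    plt = _mpl()
    vals = fit.x_loadings[:, component]
    order = np.argsort(vals)
    names = [fit.x_names[j] for j in order]
    fig, ax = plt.subplots(figsize=(6, max(4, 0.12 * len(names))))
    ax.barh(np.arange(len(names)), vals[order], color="#3b6ea5")
    ax.set_yticks(np.arange(len(names)))
    ax.set_yticklabels(names, fontsize=4)
    ax.set_xlabel(f"{fit.method} component {component + 1} loading")
    ax.axvline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_cosine_heatmap(report: ComparisonReport, path) -> None:
    """Matched-component cosine similarities for every method pair."""
    plt = _mpl()
    pairs = list(report.alignments)
    fig, axes = plt.subplots(1, len(pairs), figsize=(3.2 * len(pairs), 3), squeeze=False)
    for ax, key in zip(axes[0], pairs):
        matches = report.alignments[key]
        k = len(matches)
        mat = np.zeros((k, k))
        for mt in matches:
            mat[mt.index_a, mt.index_b] = mt.cosine
        im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"{key[0]} vs {key[1]}", fontsize=8)
        ax.set_xlabel(key[1])
        ax.set_ylabel(key[0])
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
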