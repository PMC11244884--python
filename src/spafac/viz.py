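"""Minimal plotting convenience: per-sample factor heatmaps."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_factors"]


def plot_factors(factors: np.ndarray, coords: np.ndarray, path: str | None = None,
                 title: str | None = None):
    """Scatter each factor column over the spot coordinates, one panel per factor.

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    F = np.atleast_2d(np.asarray(factors, dtype=float))
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    L = F.shape[1]
    ncol = min(L, 4)
    nrow = int(np.ceil(L / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.7 * nrow),
                             squeeze=False)
    for l in range(L):
        ax = axes[l // ncol][l % ncol]
        sc = ax.scatter(X[:, 0], X[:, 1], c=F[:, l], s=14, cmap="viridis",
                        marker="s")
        ax.set_title(f"factor {l + 1}", fontsize=9)
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(sc, ax=ax, shrink=0.8)
    for l in range(L, nrow * ncol):
        axes[l // ncol][l % ncol].axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
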