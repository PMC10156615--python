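"""Minimal figure export: effect-size heatmaps and scatter plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cartography import EffectSizeMatrix

__all__ = ["heatmap_png", "scatter_png"]


def heatmap_png(
    esm: EffectSizeMatrix,
    path,
    starred_sounds: list[str] | None = None,
    title: str = "",
) -> None:
    """Diverging heatmap of the (ordered) effect-size map.

    Sounds whose classifier survived FDR can be marked with a star.
    """
    mat = esm.ordered()
    vmax = np.nanmax(np.abs(mat.to_numpy())) or 1.0
    fig, ax = plt.subplots(
        figsize=(0.45 * len(mat.columns) + 2, 0.28 * len(mat.index) + 1.5)
    )
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=7)
    labels = [
        f"{s} *" if starred_sounds and s in starred_sounds else s for s in mat.index
    ]
    ax.set_yticks(range(len(mat.index)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="Cohen's d (case > control)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scatter_png(x, y, path, xlabel="", ylabel="", title="") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, alpha=0.6)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
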