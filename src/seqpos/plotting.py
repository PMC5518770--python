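"""Minimal matrix/bar plots for confusion and similarity structures."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .repsim import ConfusionMatrix, CrossPhaseSimilarity

_POS = ("1", "2", "3")


def plot_confusion(cm: ConfusionMatrix, path: Path | str, title: str = "") -> Path:
    """Grouped bars: proportion of predicted positions per true position,
    with the 1/3 chance line."""
    fig, ax = plt.subplots(figsize=(4, 3))
    width = 0.25
    x = np.arange(3)
    for j in range(3):
        vals = cm.proportions[:, j]
        ax.bar(x + (j - 1) * width, vals, width,
               label=f"pred {j + 1}",
               color=["0.25" if j == i else "0.7" for i in range(3)])
    ax.axhline(1 / 3, color="red", lw=1, label="chance")
    ax.set_xticks(x, [f"true {p}" for p in _POS])
    ax.set_ylabel("proportion predicted")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_similarity(sim: CrossPhaseSimilarity, path: Path | str, title: str = "") -> Path:
    """3x3 presentation x recognition pattern-correlation matrix."""
    fig, ax = plt.subplots(figsize=(3.4, 3))
    im = ax.imshow(sim.rho, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(3), [f"R{p}" for p in _POS])
    ax.set_yticks(range(3), [f"P{p}" for p in _POS])
    for i in range(3):
        for j in range(3):
            ax.text(j, i, f"{sim.rho[i, j]:.2f}", ha="center", va="center", fontsize=8)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
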