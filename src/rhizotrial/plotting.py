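"""Thin matplotlib layer: phenotype heat-maps and AMMI biplots."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .ammi import BiplotCoords
from .metrics import ScoreMatrix

__all__ = ["score_heatmap", "biplot"]


def score_heatmap(matrix: ScoreMatrix, path: Optional[str | Path] = None, ax=None):
    """Render a strain x genotype score matrix as a heat-map.

    The colour key runs from the observed minimum through the mean to the
    maximum score.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    vals = matrix.values.values
    vmin, vmax = np.nanmin(vals), np.nanmax(vals)
    mid = np.nanmean(vals)
    im = ax.imshow(vals, cmap="RdYlGn", vmin=vmin, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(matrix.values.columns)), matrix.values.columns, rotation=90)
    ax.set_yticks(range(len(matrix.values.index)), matrix.values.index)
    ax.set_title(f"{matrix.phenotype} scores")
    cbar = ax.figure.colorbar(im, ax=ax, ticks=[vmin, mid, vmax])
    cbar.set_label("scaled score")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def biplot(coords: BiplotCoords, path: Optional[str | Path] = None, ax=None):
    """Plot strain (blue) and genotype (red) scores on the first two axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for kind, colour in (("strain", "tab:blue"), ("genotype", "tab:red")):
        sub = coords.frame[coords.frame["kind"] == kind]
        ax.scatter(sub["dim1"], sub["dim2"], color=colour, label=kind, s=20)
        for row in sub.itertuples(index=False):
            ax.annotate(row.label, (row.dim1, row.dim2), fontsize=8, color=colour)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
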