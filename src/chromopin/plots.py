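"""Diagnostic plots: score distributions and segmentation overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from chromopin.plate import PlateImage
from chromopin.quantify import GridFit


def score_distribution(scores: pd.Series | np.ndarray,
                       threshold: float | None = None,
                       path: str | Path | None = None):
    """Histogram of log10(1 + score) with the hit threshold marked.

    The heavy right tail past the threshold line is the hit population;
    useful for judging whether a threshold separates the white-colony bulk
    from genuinely red colonies.
    """
    s = np.asarray(pd.Series(scores).dropna(), dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(np.log10(1.0 + s), bins=60, color="#777777")
    if threshold is not None:
        ax.axvline(np.log10(1.0 + threshold), color="crimson", ls="--",
                   label=f"threshold = {threshold:.3g}")
        ax.legend(frameon=False)
    ax.set_xlabel("log10(1 + CPRG score)")
    ax.set_ylabel("colonies")
    ax.set_yscale("log")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def grid_overlay(image: PlateImage, grid: GridFit,
                 measurements: pd.DataFrame | None = None,
                 path: str | Path | None = None):
    """Plate image with fitted grid lines and (optionally) colony markers."""
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.imshow(image.pixels)
    for y in grid.row_centers:
        ax.axhline(y, color="cyan", lw=0.4, alpha=0.6)
    for x in grid.col_centers:
        ax.axvline(x, color="cyan", lw=0.4, alpha=0.6)
    if measurements is not None:
        ok = measurements[measurements["area"] > 0]
        ax.scatter(ok["center_x"], ok["center_y"], s=6, c="lime", marker="+")
        flagged = measurements[
            measurements["flags"].str.contains("neighbor_contaminated",
                                               na=False)]
        ax.scatter(flagged["center_x"], flagged["center_y"], s=40,
                   facecolors="none", edgecolors="orange")
    ax.set_axis_off()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
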