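"""Optional static figures: single-cell heat maps and exit-aligned traces."""

from __future__ import annotations

from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dynamics import PhaseFeatures, heatmap_order
from .simulate import CellTrajectory

__all__ = ["plot_heatmap", "plot_exit_aligned"]


def plot_heatmap(cells: Sequence[CellTrajectory],
                 features: Sequence[PhaseFeatures], path: str) -> None:
    """FOXO1 and p53 heat maps, rows sorted by FOXO1 phase duration.

    Missing frames (after death) render as gray, mirroring how interrupted
    trajectories are displayed in single-cell heat-map figures.
    """
    by_id = {c.cell_id: c for c in cells}
    deaths = {c.cell_id: c.t_death for c in cells if c.t_death is not None}
    order = heatmap_order(features, deaths)
    foxo = np.vstack([by_id[i].foxo1_nf for i in order])
    p53 = np.vstack([by_id[i].p53 for i in order])
    t = cells[0].t
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, mat, title, cmap in ((axes[0], foxo, "FOXO1 nuclear fraction", "viridis"),
                                 (axes[1], p53, "nuclear p53 (a.u.)", "magma")):
        cm = plt.get_cmap(cmap).copy()
        cm.set_bad("0.6")
        im = ax.imshow(np.ma.masked_invalid(mat), aspect="auto", cmap=cm,
                       extent=(t[0] / 60, t[-1] / 60, len(order), 0))
        ax.set_title(title)
        ax.set_xlabel("time (h)")
        fig.colorbar(im, ax=ax, shrink=0.8)
    axes[0].set_ylabel("cells (sorted by FOXO1 duration)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_exit_aligned(aligned: pd.DataFrame, path: str) -> None:
    """Median FOXO1/p53 traces aligned to FOXO1 nuclear exit."""
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax2 = ax1.twinx()
    h = aligned["rel_t_min"] / 60
    ax1.plot(h, aligned["foxo1_nf_median"], color="tab:blue", label="FOXO1")
    ax2.plot(h, aligned["p53_median"], color="tab:red", label="p53")
    ax1.axvline(0, color="0.5", ls="--", lw=0.8)
    ax1.set_xlabel("time from FOXO1 nuclear exit (h)")
    ax1.set_ylabel("median FOXO1 nuclear fraction", color="tab:blue")
    ax2.set_ylabel("median nuclear p53 (a.u.)", color="tab:red")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
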