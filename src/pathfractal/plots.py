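"""Quick-look figures for the analysis outputs (PNG, matplotlib Agg)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import FDI_COLUMNS, TREATMENTS
from .stats import CorrelationMatrix, OrdinationResult


def fdi_boxplots(wide: pd.DataFrame, path: str | Path) -> None:
    """Boxplots of each FDI by treatment, with a D = 2 isotropy reference."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharey=True)
    for ax, col in zip(axes, FDI_COLUMNS):
        if col not in wide:
            ax.set_visible(False)
            continue
        data = [wide.loc[wide["treatment"] == t, col].dropna() for t in TREATMENTS]
        ax.boxplot(data, tick_labels=list(TREATMENTS))
        ax.axhline(2.0, color="red", ls="--", lw=1)
        ax.set_title(col)
    axes[0].set_ylabel("fractal dimension D")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ordination_biplot(res: OrdinationResult, path: str | Path) -> None:
    """Scores on the first two axes with variable vectors."""
    ax1, ax2 = res.scores.columns[:2]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    color_by = None
    if res.groups is not None:
        for cand in ("family", "dominant_fdi"):
            if cand in res.groups:
                color_by = res.groups[cand].to_numpy()
                break
    if color_by is not None:
        for lvl in pd.unique(color_by):
            m = color_by == lvl
            ax.scatter(res.scores[ax1][m], res.scores[ax2][m], s=8, label=str(lvl))
        ax.legend(fontsize=7)
    else:
        ax.scatter(res.scores[ax1], res.scores[ax2], s=8)
    scale = 0.8 * np.abs(res.scores[[ax1, ax2]].to_numpy()).max()
    for var in res.loadings.index:
        vx, vy = res.loadings.loc[var, ax1], res.loadings.loc[var, ax2]
        ax.arrow(0, 0, vx * scale, vy * scale, color="gray", width=0.002)
        ax.annotate(var, (vx * scale, vy * scale), fontsize=7)
    ax.set_xlabel(f"{ax1} ({res.variance_explained[0]:.1f}%)")
    ax.set_ylabel(f"{ax2} ({res.variance_explained[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def correlation_heatmap(cm: CorrelationMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(cm.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cm.variables)), cm.variables, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(cm.variables)), cm.variables, fontsize=7)
    for i in range(len(cm.variables)):
        for j in range(len(cm.variables)):
            v = cm.r.iloc[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
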