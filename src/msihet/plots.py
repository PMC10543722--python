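"""Matplotlib renderings of pipeline matrices (optional, presentation only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .compare import CohortComparison
from .dataio import PixelTable
from .segmentation import SegmentationResult
from .survgrid import GridResult

__all__ = ["grid_heatmap", "segmentation_map", "comparison_bars"]


def grid_heatmap(grid: GridResult, path) -> Path:
    """AIC over the (k, τ) grid; white squares mark the per-k best threshold."""
    mat = grid.matrix("aic")
    fig, ax = plt.subplots(figsize=(9, 4))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu",
                   extent=[mat.columns.min(), mat.columns.max(), mat.index.max() + 0.5,
                           mat.index.min() - 0.5])
    best = grid.best_per_k()
    if len(best):
        ax.scatter(best["threshold"], best["k"], marker="s", s=30,
                   facecolors="white", edgecolors="black", label="best per k")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("presence threshold τ")
    ax.set_ylabel("k")
    fig.colorbar(im, ax=ax, label="AIC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def segmentation_map(table: PixelTable, seg: SegmentationResult, path,
                     max_cores: int = 12) -> Path:
    """Indexed-color per-core maps of cluster labels (first ``max_cores`` cores)."""
    df = table.frame[["pixel_id", "core_id", "x", "y"]].copy()
    df["cluster"] = seg.labels.loc[df["pixel_id"].to_numpy()].to_numpy()
    cores = list(dict.fromkeys(df["core_id"]))[:max_cores]
    ncol = min(4, len(cores))
    nrow = int(np.ceil(len(cores) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False)
    cmap = plt.get_cmap("tab20", seg.k)
    for ax, core in zip(axes.ravel(), cores):
        sub = df[df["core_id"] == core]
        ax.scatter(sub["x"], sub["y"], c=sub["cluster"], cmap=cmap, vmin=1, vmax=seg.k,
                   s=6, marker="s")
        ax.set_title(str(core), fontsize=8)
        ax.set_aspect("equal")
        ax.axis("off")
    for ax in axes.ravel()[len(cores):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def comparison_bars(comparison: CohortComparison, path) -> Path:
    """Per-cluster cohort pixel-share bars (two-cohort comparison)."""
    t = comparison.table
    a, b = comparison.cohort_a, comparison.cohort_b
    x = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.bar(x - 0.2, t[f"pixel_share_{a}"], width=0.4, color="black", label=a)
    ax.bar(x + 0.2, t[f"pixel_share_{b}"], width=0.4, color="white",
           edgecolor="black", label=b)
    ax.set_xticks(x, [f"S{c}" for c in t["cluster"]])
    ax.set_ylabel("share of cluster pixels")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
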