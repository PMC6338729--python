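"""Static figures: PCA marker scatter, QSep heatmap, theta weight summary."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import UNKNOWN, MarkerAnnotation, ProfileDataset, pca_project

__all__ = ["pca_scatter", "qsep_heatmap", "theta_summary"]


def pca_scatter(dataset: ProfileDataset, markers: MarkerAnnotation, path) -> None:
    """PC1/PC2 scatter with markers coloured by class, unknowns in grey."""
    res = pca_project(dataset, 2)
    fig, ax = plt.subplots(figsize=(7, 6))
    labels = markers.class_series(dataset.accessions)
    unk = labels == UNKNOWN
    ax.scatter(
        res.scores.loc[unk, "PC1"], res.scores.loc[unk, "PC2"],
        s=6, c="lightgrey", label=None, zorder=1,
    )
    cmap = plt.get_cmap("tab20")
    for i, cls in enumerate(markers.classes):
        sel = labels == cls
        if sel.any():
            ax.scatter(
                res.scores.loc[sel, "PC1"], res.scores.loc[sel, "PC2"],
                s=14, color=cmap(i % 20), label=cls, zorder=2,
            )
    vf = res.variance_fraction
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}% variance)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}% variance)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qsep_heatmap(normalised: pd.DataFrame, path) -> None:
    """Heatmap of normalised between/within cluster distances."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(normalised.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(normalised.columns)), normalised.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(normalised.index)), normalised.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="normalised distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def theta_summary(frequencies: pd.DataFrame, path) -> None:
    """Bubble plot of per-class weight frequencies over iterations."""
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(frequencies) + 1.5))
    for yi, cls in enumerate(frequencies.index):
        for xi, w in enumerate(frequencies.columns):
            f = frequencies.loc[cls, w]
            if f > 0:
                ax.scatter(xi, yi, s=2000 * f, alpha=0.6, color="tab:blue")
                ax.annotate(f"{f:.2f}", (xi, yi), ha="center", va="center", fontsize=7)
    ax.set_xticks(range(len(frequencies.columns)), [str(w) for w in frequencies.columns])
    ax.set_yticks(range(len(frequencies.index)), frequencies.index, fontsize=8)
    ax.set_xlabel("weight")
    ax.set_xlim(-0.5, len(frequencies.columns) - 0.5)
    ax.set_ylim(-0.5, len(frequencies.index) - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
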