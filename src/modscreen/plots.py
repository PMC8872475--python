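"""Presentation plots: the 2-D cluster embedding and per-cluster eye sizes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .clustering import ClusterModel, ThresholdSpec, embed_2d
from .io_formats import PhenotypeTable
from .preprocess import StrainExpression

__all__ = ["plot_embedding", "plot_cluster_eye_sizes"]


def plot_embedding(data: StrainExpression, model: ClusterModel,
                   path: str | Path) -> None:
    """PCA scatter of strains colored by cluster (presentation only)."""
    coords = embed_2d(data)
    fig, ax = plt.subplots(figsize=(7, 6))
    for label in range(1, model.k + 1):
        mask = model.labels == label
        ax.scatter(coords[mask, 0], coords[mask, 1], s=18,
                   label=f"cluster {label} (n={mask.sum()})")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("Strain expression profiles, K-Means clusters")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cluster_eye_sizes(model: ClusterModel, phenotypes: PhenotypeTable,
                           spec: ThresholdSpec, path: str | Path,
                           clusters: list[int] | None = None) -> None:
    """Eye sizes per strain for selected clusters, with quadrant thresholds."""
    sizes = phenotypes.to_series()
    clusters = clusters or list(range(1, model.k + 1))
    fig, ax = plt.subplots(figsize=(8, 5))
    for label in clusters:
        members = model.members(label)
        ax.scatter(range(len(members)), [sizes.loc[s] for s in members],
                   s=20, label=f"cluster {label}")
    ax.axhline(spec.upper, color="firebrick", ls="--", lw=1,
               label=f"upper = {spec.upper:.2f}")
    ax.axhline(spec.lower, color="steelblue", ls="--", lw=1,
               label=f"lower = {spec.lower:.2f}")
    ax.set_xlabel("strain (index within cluster)")
    ax.set_ylabel("mean eye size (pixels x 10^3)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
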