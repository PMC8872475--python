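"""K-Means strain clustering and phenotype-quadrant outlier-cluster selection.

Strains are clustered by their replicate-averaged expression profiles with
Lloyd's algorithm (squared Euclidean distance over all genes, no gene
weighting, no prior dimensionality reduction). Initialization draws k distinct
strains uniformly without replacement; the best of several seeded restarts by
within-cluster sum of squares (WSS) is returned. Silhouette widths and a
two-component PCA embedding are provided as advisory / presentation aids only.

The eye-size range is partitioned into four quadrants: the upper threshold is
one quadrant below the maximum and the lower threshold one quadrant above the
minimum. The cluster with the most strains strictly above the upper threshold
is the high-eye-size outlier cluster, and symmetrically for the lower one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .io_formats import PhenotypeTable
from .preprocess import StrainExpression

__all__ = [
    "ClusterModel",
    "ThresholdSpec",
    "OutlierClusters",
    "kmeans",
    "silhouette",
    "silhouette_sweep",
    "embed_2d",
    "compute_thresholds",
    "identify_outliers",
]


@dataclass
class ClusterModel:
    """Fitted K-Means model over strains; labels run 1..k."""

    k: int
    strain_ids: list[int]
    labels: np.ndarray          # per-strain label in 1..k
    centroids: np.ndarray       # shape (k, n_genes)
    sizes: np.ndarray           # shape (k,)
    wss: float
    seed: int
    n_iter: int
    wss_trace: list[float] = field(default_factory=list)

    def assignments(self) -> dict[int, int]:
        return {s: int(c) for s, c in zip(self.strain_ids, self.labels)}

    def members(self, label: int) -> list[int]:
        return [s for s, c in zip(self.strain_ids, self.labels) if c == label]


def _assign(data: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels (0-based) and squared distances to own centroid."""
    # ||x - c||^2 expanded; data (n,g), centroids (k,g)
    d2 = (
        np.einsum("ij,ij->i", data, data)[:, None]
        - 2.0 * data @ centroids.T
        + np.einsum("ij,ij->i", centroids, centroids)[None, :]
    )
    d2 = np.maximum(d2, 0.0)
    labels = np.argmin(d2, axis=1)
    return labels, d2[np.arange(len(data)), labels]


def _lloyd(data: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    n = data.shape[0]
    centroids = data[rng.choice(n, size=k, replace=False)].copy()
    prev_labels = None
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        labels, d2 = _assign(data, centroids)
        # repair: re-seed an emptied centroid at the point farthest from its
        # current centroid (this can only lower the objective)
        for j in range(k):
            if not (labels == j).any():
                centroids[j] = data[int(np.argmax(d2))]
                labels, d2 = _assign(data, centroids)
        trace.append(float(d2.sum()))
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            break  # no reassignment: centroids already equal the cluster means
        prev_labels = labels
        for j in range(k):
            centroids[j] = data[labels == j].mean(axis=0)
    return prev_labels, centroids, trace[-1], it, trace


def kmeans(data: StrainExpression, k: int, seed: int = 0,
           n_restarts: int = 10) -> ClusterModel:
    """Best-of-restarts Lloyd K-Means on the strain x gene matrix.

    Runs ``n_restarts`` seeded initializations (k distinct strains each) to
    convergence (no reassignment) and returns the restart with minimum WSS.
    Deterministic given (data, k, seed, n_restarts).
    """
    n = len(data.strain_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n} (number of strains), got {k}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    X = np.asarray(data.values, dtype=float)
    master = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        labels, centroids, wss, n_iter, trace = _lloyd(X, k, rng)
        if best is None or wss < best[2]:
            best = (labels, centroids, wss, n_iter, trace)
    labels, centroids, wss, n_iter, trace = best
    sizes = np.bincount(labels, minlength=k)
    return ClusterModel(
        k=k,
        strain_ids=list(data.strain_ids),
        labels=labels + 1,
        centroids=centroids,
        sizes=sizes,
        wss=wss,
        seed=seed,
        n_iter=n_iter,
        wss_trace=trace,
    )


def silhouette(data: StrainExpression, model: ClusterModel) -> tuple[np.ndarray, float]:
    """Per-strain silhouette widths and their mean.

    Widths lie in [-1, 1]; a strain alone in its cluster gets width 0 by the
    singleton convention. Undefined for k = 1.
    """
    if model.k < 2:
        raise ValueError("silhouette is undefined for k = 1")
    if model.k == len(data.strain_ids):
        # every cluster is a singleton: width 0 by the singleton convention
        widths = np.zeros(len(data.strain_ids))
        return widths, 0.0
    widths = silhouette_samples(np.asarray(data.values, dtype=float),
                                model.labels)
    return widths, float(widths.mean())


def silhouette_sweep(data: StrainExpression, ks=range(2, 9), seed: int = 0,
                     n_restarts: int = 10) -> dict[int, float]:
    """Mean silhouette width per candidate k — advisory only.

    The screening default of k = 6 is a deliberate override: with few strains
    the sweep tends to recommend k = 2, which is too coarse to isolate the
    phenotype-outlier groupings.
    """
    out: dict[int, float] = {}
    for k in ks:
        model = kmeans(data, k, seed=seed, n_restarts=n_restarts)
        out[k] = silhouette(data, model)[1]
    return out


def embed_2d(data: StrainExpression) -> np.ndarray:
    """First two principal-component scores per strain (plots only).

    Never used in clustering or outlier selection.
    """
    X = np.asarray(data.values, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("embedding needs at least 2 strains and 2 genes")
    return PCA(n_components=2).fit_transform(X)


@dataclass
class ThresholdSpec:
    """Quadrant thresholds over the eye-size range."""

    min_size: float
    max_size: float

    @property
    def partition(self) -> float:
        return (self.max_size - self.min_size) / 4.0

    @property
    def upper(self) -> float:
        return self.max_size - self.partition

    @property
    def lower(self) -> float:
        return self.min_size + self.partition

    def as_dict(self) -> dict:
        return {"min": self.min_size, "max": self.max_size,
                "partition": self.partition, "upper": self.upper, "lower": self.lower}


def compute_thresholds(phenotypes: PhenotypeTable) -> ThresholdSpec:
    """Quadrant thresholds from the observed eye-size extremes.

    partition = (max - min)/4; upper = max - partition; lower = min + partition.
    """
    if len(phenotypes) < 2:
        raise ValueError("thresholds need at least 2 strains")
    sizes = phenotypes.eye_sizes
    return ThresholdSpec(min_size=float(sizes.min()), max_size=float(sizes.max()))


@dataclass
class OutlierClusters:
    high_cluster: int
    low_cluster: int
    counts_above: dict[int, int]
    counts_below: dict[int, int]


def identify_outliers(model: ClusterModel, phenotypes: PhenotypeTable,
                      spec: ThresholdSpec) -> OutlierClusters:
    """Pick the clusters with the most strains strictly beyond each threshold.

    Comparisons are strict (> upper, < lower): a strain exactly at a threshold
    is not counted. Ties for either argmax raise (a deterministic failure
    rather than a silent choice), as does the absence of any strain beyond a
    threshold.
    """
    sizes = phenotypes.to_series()
    missing = [s for s in model.strain_ids if s not in sizes.index]
    if missing:
        raise ValueError(f"clustered strain(s) without phenotype: {missing}")
    counts_above = {c: 0 for c in range(1, model.k + 1)}
    counts_below = {c: 0 for c in range(1, model.k + 1)}
    for s, c in zip(model.strain_ids, model.labels):
        v = float(sizes.loc[s])
        if v > spec.upper:
            counts_above[int(c)] += 1
        if v < spec.lower:
            counts_below[int(c)] += 1

    def _argmax(counts: dict[int, int], side: str) -> int:
        best = max(counts.values())
        if best == 0:
            raise ValueError(f"no outlier cluster identifiable: no strain {side} threshold")
        tied = [c for c, v in counts.items() if v == best]
        if len(tied) > 1:
            raise ValueError(f"tied outlier clusters {tied} ({side} threshold)")
        return tied[0]

    high = _argmax(counts_above, "above upper")
    low = _argmax(counts_below, "below lower")
    if high == low:
        raise ValueError(
            f"cluster {high} maximizes both outlier counts; high and low "
            "outlier clusters must differ")
    return OutlierClusters(high_cluster=high, low_cluster=low,
                           counts_above=counts_above, counts_below=counts_below)
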