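"""Ranking, significance filtering and three-method intersection.

For each outlier cluster and each correlation method, genes are filtered to
p < alpha, ranked by decreasing absolute coefficient and truncated to the top
k (default 20). The candidate-modifier table is the per-cluster intersection
of the three method lists, unioned over the two outlier clusters; genes
selected under both clusters keep both sets of statistics.

``run_pipeline`` drives the whole screen: read -> intersect strains -> drop
incomplete replicates -> average -> K-Means -> thresholds -> outlier clusters
-> correlate (3 methods x 2 clusters) -> top-k -> intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, preprocess, clustering, correlation
from .correlation import METHODS, CorrelationResult

__all__ = [
    "ScreenConfig",
    "PipelineError",
    "PipelineResult",
    "top_k",
    "intersect_methods",
    "run_pipeline",
]


@dataclass
class ScreenConfig:
    """All tunables of the screen; every field is mirrored by a CLI flag."""

    k: int = 6                      # number of K-Means clusters
    top_k: int = 20                 # genes kept per method per cluster
    alpha: float = 0.05             # per-test significance cutoff (no FDR)
    seed: int = 0
    n_restarts: int = 10
    required_replicates: int = 2
    allow_partial_replicates: bool = False
    kendall_variant: str = "tau_b"
    all_strains: bool = False       # correlate over all strains, not per cluster
    pool_clusters: bool = False     # union method lists across clusters first
    rank_then_filter: bool = False  # truncate to top-k before the alpha filter
    silhouette_sweep: bool = False  # report advisory mean widths for k = 2..8


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def top_k(results: list[CorrelationResult], k: int, alpha: float,
          rank_then_filter: bool = False) -> list[CorrelationResult]:
    """Significant genes ranked by |coefficient|, truncated to k.

    Ties in |coefficient| break by ascending p-value, then lexicographic gene
    ID, so the ranking is deterministic. Constant-expression genes never rank.
    May return fewer than k genes.
    """
    if not results:
        raise ValueError("no correlation results to rank")
    if k < 1:
        raise ValueError("k must be >= 1")
    usable = [r for r in results if not r.constant and np.isfinite(r.coefficient)]
    key = lambda r: (-abs(r.coefficient), r.p_value, r.gene_id)
    if rank_then_filter:
        ranked = sorted(usable, key=key)[:k]
        return [r for r in ranked if r.p_value < alpha]
    significant = [r for r in usable if r.p_value < alpha]
    return sorted(significant, key=key)[:k]


_PREFIX = {"pearson": "pearson_r", "kendall": "kendall_tau", "spearman": "spearman_r"}


def intersect_methods(per_method_lists: dict[str, list[CorrelationResult]],
                      cluster_label: int | None = None) -> pd.DataFrame:
    """Candidate rows for one cluster: union of the method lists, flagged.

    One row per gene carrying each method's coefficient, p-value and rank
    (rank within that method's list, 1-based; absent where the gene did not
    make the list). ``in_intersection`` marks genes present in all three
    lists. The intersection itself equals plain set intersection of the
    three gene-ID lists.
    """
    missing = [m for m in METHODS if m not in per_method_lists]
    if missing:
        raise ValueError(f"missing method list(s): {missing}")
    rows: dict[str, dict] = {}
    for method in METHODS:
        for rank, res in enumerate(per_method_lists[method], start=1):
            row = rows.setdefault(res.gene_id, {"gene": res.gene_id,
                                                "cluster": cluster_label})
            prefix = _PREFIX[method]
            row[prefix] = res.coefficient
            row[f"{method}_p"] = res.p_value
            row[f"{method}_rank"] = rank
    shared = set.intersection(*(set(r.gene_id for r in per_method_lists[m])
                                for m in METHODS))
    for gene, row in rows.items():
        row["in_intersection"] = gene in shared
    df = pd.DataFrame(list(rows.values()))
    if df.empty:
        df = pd.DataFrame(columns=io_formats._CAND_COLUMNS)
    for col in io_formats._CAND_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[io_formats._CAND_COLUMNS]
    return df.sort_values(["in_intersection", "gene"],
                          ascending=[False, True]).reset_index(drop=True)


@dataclass
class PipelineResult:
    candidates: pd.DataFrame          # all ranked genes, both clusters
    intersection: pd.DataFrame        # rows with in_intersection = True
    model: clustering.ClusterModel
    thresholds: clustering.ThresholdSpec
    outliers: clustering.OutlierClusters
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(phenopath: str | Path, exprpath: str | Path,
                 config: ScreenConfig | None = None) -> PipelineResult:
    """Execute the full screen on a phenotype file and an expression file."""
    cfg = config or ScreenConfig()
    report = preprocess.FilterReport()

    pheno = _stage("read_phenotype")(io_formats.read_phenotype_table)(phenopath)
    expr = _stage("read_expression")(io_formats.read_expression_matrix)(exprpath)
    pheno, expr = _stage("intersect_strains")(preprocess.intersect_strains)(
        pheno, expr, report)
    expr = _stage("drop_incomplete")(preprocess.drop_incomplete_strains)(
        expr, cfg.required_replicates, report, cfg.allow_partial_replicates)
    pheno = pheno.subset(expr.strain_numbers)
    data = _stage("average_replicates")(preprocess.average_replicates)(expr)

    if cfg.k < 2:
        raise PipelineError("kmeans", ValueError(
            "screening needs k >= 2 clusters to tell outlier groupings apart"))
    model = _stage("kmeans")(clustering.kmeans)(
        data, cfg.k, seed=cfg.seed, n_restarts=cfg.n_restarts)
    sweep = None
    if cfg.silhouette_sweep:
        sweep = _stage("silhouette")(clustering.silhouette_sweep)(
            data, seed=cfg.seed, n_restarts=cfg.n_restarts)
    thresholds = _stage("thresholds")(clustering.compute_thresholds)(pheno)
    outliers = _stage("identify_outliers")(clustering.identify_outliers)(
        model, pheno, thresholds)

    cluster_strains = {
        label: model.members(label)
        for label in (outliers.high_cluster, outliers.low_cluster)
    }

    def _screen_cluster(label: int, strains: list[int]) -> pd.DataFrame:
        lists = {}
        for method in METHODS:
            results = _stage(f"correlate_{method}")(correlation.correlate_genes)(
                data, pheno, method,
                strain_set=None if cfg.all_strains else strains,
                kendall_variant=cfg.kendall_variant)
            lists[method] = _stage("top_k")(top_k)(
                results, cfg.top_k, cfg.alpha, cfg.rank_then_filter)
        return _stage("intersect_methods")(intersect_methods)(lists, label)

    if cfg.pool_clusters:
        # union each method's per-cluster lists before intersecting
        pooled: dict[str, list[CorrelationResult]] = {m: [] for m in METHODS}
        for label, strains in cluster_strains.items():
            for method in METHODS:
                results = _stage(f"correlate_{method}")(correlation.correlate_genes)(
                    data, pheno, method,
                    strain_set=None if cfg.all_strains else strains,
                    kendall_variant=cfg.kendall_variant)
                kept = _stage("top_k")(top_k)(
                    results, cfg.top_k, cfg.alpha, cfg.rank_then_filter)
                seen = {r.gene_id for r in pooled[method]}
                pooled[method].extend(r for r in kept if r.gene_id not in seen)
        candidates = _stage("intersect_methods")(intersect_methods)(pooled, None)
    else:
        frames = [_screen_cluster(label, strains)
                  for label, strains in cluster_strains.items()]
        candidates = pd.concat(frames, ignore_index=True)

    intersection = candidates[candidates["in_intersection"].astype(bool)]
    intersection = intersection.reset_index(drop=True)

    manifest = {
        "config": asdict(cfg),
        "n_strains_analyzed": len(data),
        "n_genes": len(data.gene_ids),
        "filter_report": report.as_dict(),
        "constant_genes": data.constant_genes(),
        "thresholds": thresholds.as_dict(),
        "cluster_sizes": {int(c): int(s) for c, s in
                          zip(range(1, model.k + 1), model.sizes)},
        "outlier_clusters": {
            "high": outliers.high_cluster, "low": outliers.low_cluster,
            "counts_above": outliers.counts_above,
            "counts_below": outliers.counts_below,
        },
        "silhouette_sweep": sweep,
        "kmeans": {"wss": model.wss, "n_iter": model.n_iter, "seed": model.seed},
        "n_candidates": int(len(candidates)),
        "n_intersection": int(intersection["gene"].nunique()),
    }
    return PipelineResult(candidates=candidates, intersection=intersection,
                          model=model, thresholds=thresholds, outliers=outliers,
                          manifest=manifest)
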