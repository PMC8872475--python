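"""Per-gene correlation of expression with eye size.

Three coefficients are computed between a strain phenotype vector (mean eye
size) and a gene's replicate-averaged expression vector:

* **Pearson's r** — r = sum(z_x * z_y) / (n - 1) over the standardized scores,
  i.e. the usual product-moment coefficient; two-sided p from the exact-null
  t statistic t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.
* **Kendall's tau** — pair concordance. tau_a = (n_c - n_d) / n_0 with
  n_0 = n(n-1)/2 unordered pairs; tau_b divides by the tie-corrected
  denominator sqrt((n_0 - T_x)(n_0 - T_y)). Two-sided p from the normal
  approximation to the concordance statistic S = n_c - n_d (with the standard
  tie adjustment to var(S) for tau_b).
* **Spearman's r_s** — Pearson's formula applied to the rank vectors, average
  ranks for ties; p via the same t approximation on n - 2 df.

All three are implemented directly from their definitions (pair counting is
the O(n^2) sign-matrix form); SciPy supplies only distribution tails and rank
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .io_formats import PhenotypeTable
from .preprocess import StrainExpression

__all__ = [
    "CorrelationResult",
    "pearson",
    "kendall",
    "spearman",
    "correlate_genes",
    "METHODS",
]

METHODS = ("pearson", "kendall", "spearman")

Method = Literal["pearson", "kendall", "spearman"]


@dataclass
class CorrelationResult:
    gene_id: str
    method: Method
    coefficient: float
    p_value: float
    n: int
    constant: bool = False
    detail: dict | None = None  # for Kendall: n_c, n_d, n_0


def _check_vectors(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    return x, y


def _t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    r = float(np.dot(zx, zy) / (len(x) - 1))
    return min(1.0, max(-1.0, r))


def pearson(x: Sequence[float], y: Sequence[float], gene_id: str = "") -> CorrelationResult:
    x, y = _check_vectors(x, y)
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    r = _pearson_r(x, y)
    return CorrelationResult(gene_id, "pearson", r, _t_pvalue(r, len(x)), len(x))


def _kendall_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int, int]:
    """(n_c, n_d, n_0, T_x, T_y) by explicit pair enumeration (vectorized)."""
    n = len(x)
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    prod = sx * sy
    iu = np.triu_indices(n, k=1)
    nc = int((prod[iu] > 0).sum())
    nd = int((prod[iu] < 0).sum())
    n0 = n * (n - 1) // 2
    tx = int((sx[iu] == 0).sum())
    ty = int((sy[iu] == 0).sum())
    return nc, nd, n0, tx, ty


def _kendall_var_s(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-adjusted null variance of S = n_c - n_d (normal approximation)."""
    n = len(x)

    def _tie_terms(v: np.ndarray) -> tuple[float, float, float]:
        _, cnt = np.unique(v, return_counts=True)
        t = cnt[cnt > 1].astype(float)
        return (
            float(np.sum(t * (t - 1) * (2 * t + 5))),
            float(np.sum(t * (t - 1) * (t - 2))),
            float(np.sum(t * (t - 1))),
        )

    a1, b1, c1 = _tie_terms(x)
    a2, b2, c2 = _tie_terms(y)
    v0 = n * (n - 1) * (2 * n + 5)
    var = (v0 - a1 - a2) / 18.0
    var += b1 * b2 / (9.0 * n * (n - 1) * (n - 2))
    var += c1 * c2 / (2.0 * n * (n - 1))
    return var


def kendall(x: Sequence[float], y: Sequence[float], gene_id: str = "",
            variant: Literal["tau_a", "tau_b"] = "tau_b") -> CorrelationResult:
    x, y = _check_vectors(x, y)
    n = len(x)
    nc, nd, n0, tx, ty = _kendall_counts(x, y)
    s = nc - nd
    if variant == "tau_a":
        tau = s / n0
        var_s = n * (n - 1) * (2 * n + 5) / 18.0
    elif variant == "tau_b":
        denom = np.sqrt(float(n0 - tx) * float(n0 - ty))
        if denom == 0:
            raise ValueError("constant input: Kendall tau_b undefined")
        tau = s / denom
        var_s = _kendall_var_s(x, y)
    else:
        raise ValueError(f"unknown Kendall variant {variant!r}")
    if var_s <= 0:
        p = 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(s) / np.sqrt(var_s)))
    return CorrelationResult(
        gene_id, "kendall", float(tau), min(p, 1.0), n,
        detail={"n_c": nc, "n_d": nd, "n_0": n0, "ties_x": tx, "ties_y": ty,
                "variant": variant},
    )


def spearman(x: Sequence[float], y: Sequence[float], gene_id: str = "") -> CorrelationResult:
    x, y = _check_vectors(x, y)
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if rx.std(ddof=1) == 0 or ry.std(ddof=1) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rs = _pearson_r(rx, ry)
    return CorrelationResult(gene_id, "spearman", rs, _t_pvalue(rs, len(x)), len(x))


def correlate_genes(
    data: StrainExpression,
    phenotypes: PhenotypeTable,
    method: Method,
    strain_set: Iterable[int] | None = None,
    kendall_variant: Literal["tau_a", "tau_b"] = "tau_b",
) -> list[CorrelationResult]:
    """One correlation per gene over exactly the selected strains.

    ``strain_set`` defaults to all strains of ``data``. Genes whose expression
    is constant over the selection are reported with a NaN coefficient and the
    ``constant`` flag set, never dropped silently.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    strains = list(strain_set) if strain_set is not None else list(data.strain_ids)
    if not strains:
        raise ValueError("strain_set is empty")
    have = set(data.strain_ids)
    sizes = phenotypes.to_series()
    missing = [s for s in strains if s not in have or s not in sizes.index]
    if missing:
        raise ValueError(f"strain(s) missing from expression or phenotype: {missing}")
    sub = data.subset_strains(strains)
    x = sizes.loc[sub.strain_ids].to_numpy(dtype=float)
    n = len(x)
    results: list[CorrelationResult] = []
    for j, gene in enumerate(sub.gene_ids):
        y = sub.values[:, j]
        if np.all(y == y[0]):
            results.append(CorrelationResult(gene, method, float("nan"),
                                             float("nan"), n, constant=True))
            continue
        if method == "pearson":
            results.append(pearson(x, y, gene))
        elif method == "kendall":
            results.append(kendall(x, y, gene, variant=kendall_variant))
        else:
            results.append(spearman(x, y, gene))
    return results
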