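"""Strain filtering and replicate averaging.

The two input tables cover overlapping but unequal strain panels, and some
strains lack one of their replicate columns. The pipeline keeps only strains
present in both tables, drops strains with incomplete replicates (the strict
default; a lenient mode averages whatever replicates are present), and
averages replicate expression into one strain x gene matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, PhenotypeTable, ral_form

__all__ = [
    "StrainExpression",
    "FilterReport",
    "intersect_strains",
    "drop_incomplete_strains",
    "average_replicates",
]


@dataclass
class StrainExpression:
    """Replicate-averaged expression: one row per strain, one column per gene."""

    strain_ids: list[int]
    gene_ids: list[str]
    values: np.ndarray  # shape (n_strains, n_genes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.strain_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match strains x genes")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite averaged expression value")

    def __len__(self) -> int:
        return len(self.strain_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.strain_ids, name="strain"),
                            columns=pd.Index(self.gene_ids, name="gene"))

    def subset_strains(self, strains) -> "StrainExpression":
        keep = set(strains)
        idx = [i for i, s in enumerate(self.strain_ids) if s in keep]
        return StrainExpression([self.strain_ids[i] for i in idx], list(self.gene_ids),
                                self.values[idx])

    def constant_genes(self) -> list[str]:
        """Genes with zero variance across strains (flagged, never dropped)."""
        if not len(self.strain_ids):
            return []
        spread = self.values.max(axis=0) - self.values.min(axis=0)
        return [g for g, s in zip(self.gene_ids, spread) if s == 0.0]


@dataclass
class FilterReport:
    """What was removed during preprocessing, and why."""

    pheno_only: list[int] = field(default_factory=list)
    expr_only: list[int] = field(default_factory=list)
    incomplete_replicates: list[int] = field(default_factory=list)
    non_finite: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "phenotype_only_strains": [ral_form(s) for s in self.pheno_only],
            "expression_only_strains": [ral_form(s) for s in self.expr_only],
            "incomplete_replicate_strains": [ral_form(s) for s in self.incomplete_replicates],
            "non_finite_value_strains": [ral_form(s) for s in self.non_finite],
        }


def intersect_strains(
    phenotypes: PhenotypeTable,
    expr: ExpressionMatrix,
    report: FilterReport | None = None,
) -> tuple[PhenotypeTable, ExpressionMatrix]:
    """Restrict both tables to the strains featured in both datasets.

    Relative order within each table is preserved. Raises if the two panels
    share no strain at all.
    """
    pheno_set = set(phenotypes.strain_ids)
    expr_set = set(expr.strain_numbers)
    common = pheno_set & expr_set
    if not common:
        raise ValueError(
            f"no common strains between phenotype table ({len(pheno_set)} strains) "
            f"and expression matrix ({len(expr_set)} strains)")
    if report is not None:
        report.pheno_only = sorted(pheno_set - common)
        report.expr_only = sorted(expr_set - common)
    return phenotypes.subset(common), expr.subset_strains(common)


def drop_incomplete_strains(
    expr: ExpressionMatrix,
    required_replicates: int = 2,
    report: FilterReport | None = None,
    allow_partial_replicates: bool = False,
) -> ExpressionMatrix:
    """Remove strains that cannot be averaged over the required replicates.

    A strain is removed when it has fewer than ``required_replicates`` columns
    (e.g. ``line_513:2`` present without ``line_513:1``) or when any of its
    stored values is missing. With ``allow_partial_replicates`` the column-count
    requirement is waived (one replicate suffices) but fully missing values
    still remove the strain.
    """
    if required_replicates < 1:
        raise ValueError("required_replicates must be >= 1")
    counts = expr.replicate_counts()
    need = 1 if allow_partial_replicates else required_replicates
    short = {s for s, c in counts.items() if c < need}
    bad_value: set[int] = set()
    if expr.values.size:
        nan_cols = np.isnan(expr.values).any(axis=0)
        for i, flag in enumerate(nan_cols):
            if flag:
                bad_value.add(expr.columns[i][0])
    removed = short | bad_value
    if report is not None:
        report.incomplete_replicates = sorted(short)
        report.non_finite = sorted(bad_value - short)
    keep = [s for s in expr.strain_numbers if s not in removed]
    return expr.subset_strains(keep)


def average_replicates(expr: ExpressionMatrix) -> StrainExpression:
    """Arithmetic mean of each strain's replicate columns, per gene."""
    strains = expr.strain_numbers
    frame = expr.to_frame()
    if not strains:
        return StrainExpression([], list(expr.gene_ids),
                                np.empty((0, len(expr.gene_ids))))
    # groupby over the strain level of the column MultiIndex, order preserved
    averaged = frame.T.groupby(level="strain", sort=False).mean().T
    averaged = averaged[strains]
    return StrainExpression(strains, list(expr.gene_ids), averaged.to_numpy().T)
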