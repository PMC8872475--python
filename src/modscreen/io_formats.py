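"""Readers and writers for the strain phenotype and expression table dialects.

Two input formats are supported:

* a **phenotype table** with two columns, strain name (``RAL021`` style) and
  mean eye size in pixels x 10^3, optionally with thousands separators
  (``19,976.8``);
* a **wide expression matrix** whose first column holds gene IDs (``FBgn`` or
  ``XLOC`` prefixes) and whose remaining columns are per-replicate strain
  measurements named ``line_<N>:<rep>``.

Strain identifiers are canonicalized to their integer strain number so the two
naming conventions (``RAL021`` vs ``line_21:1``) can be joined.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "ExpressionMatrix",
    "canonical_strain_number",
    "ral_form",
    "line_form",
    "read_phenotype_table",
    "read_expression_matrix",
    "write_phenotype_table",
    "write_expression_matrix",
    "write_candidate_table",
    "read_candidate_table",
    "write_cluster_assignments",
    "write_run_manifest",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when an input table violates its dialect."""


_RAL_RE = re.compile(r"^(?:RAL|ral)_?0*(\d+)$")
_LINE_RE = re.compile(r"^line_0*(\d+)(?::(\d+))?$")
_NUM_RE = re.compile(r"^0*(\d+)$")


def canonical_strain_number(ident: str | int) -> int:
    """Return the integer strain number behind any accepted identifier form.

    ``RAL021``, ``line_21``, ``line_21:1`` and ``21`` all map to 21.
    Canonicalization is idempotent: feeding the integer back in is a no-op.
    """
    if isinstance(ident, (int, np.integer)):
        if ident <= 0:
            raise FormatError(f"strain number must be positive, got {ident}")
        return int(ident)
    s = str(ident).strip()
    for rx in (_RAL_RE, _LINE_RE, _NUM_RE):
        m = rx.match(s)
        if m:
            n = int(m.group(1))
            if n <= 0:
                raise FormatError(f"strain number must be positive in {ident!r}")
            return n
    raise FormatError(f"unrecognized strain identifier {ident!r}")


def ral_form(number: int) -> str:
    """Zero-padded ``RAL`` display form, as used in the phenotype table."""
    return f"RAL{number:03d}"


def line_form(number: int, replicate: int | None = None) -> str:
    """``line_<N>`` display form; with a replicate index, ``line_<N>:<rep>``."""
    base = f"line_{number}"
    return base if replicate is None else f"{base}:{replicate}"


@dataclass
class PhenotypeTable:
    """Strain -> mean eye size (pixels x 10^3), insertion order preserved."""

    strain_ids: list[int]
    eye_sizes: np.ndarray  # shape (n_strains,)

    def __post_init__(self) -> None:
        self.eye_sizes = np.asarray(self.eye_sizes, dtype=float)
        if len(self.strain_ids) != len(self.eye_sizes):
            raise ValueError("strain_ids and eye_sizes length mismatch")
        seen: set[int] = set()
        for s in self.strain_ids:
            if s in seen:
                raise FormatError(f"duplicate strain {ral_form(s)}")
            seen.add(s)
        if len(self.eye_sizes) and not np.all(self.eye_sizes > 0):
            bad = [ral_form(s) for s, v in zip(self.strain_ids, self.eye_sizes) if not v > 0]
            raise FormatError(f"non-positive eye size for strain(s) {', '.join(bad)}")

    def __len__(self) -> int:
        return len(self.strain_ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.eye_sizes, index=pd.Index(self.strain_ids, name="strain"),
                         name="eye_size")

    def subset(self, strains: Iterable[int]) -> "PhenotypeTable":
        keep = set(strains)
        ids = [s for s in self.strain_ids if s in keep]
        sizes = self.to_series().loc[ids].to_numpy()
        return PhenotypeTable(ids, sizes)

    def eye_size(self, strain: int) -> float:
        return float(self.to_series().loc[strain])


@dataclass
class ExpressionMatrix:
    """Gene x replicate-column raw expression.

    ``columns`` is an ordered list of ``(strain_number, replicate_index)``
    pairs; ``values`` has shape (n_genes, n_columns). NaN cells (empty fields
    in the source file) are tolerated here and resolved in preprocessing.
    """

    gene_ids: list[str]
    columns: list[tuple[int, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.columns)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.columns)} columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = pd.Index(self.gene_ids)
            dup = dup[dup.duplicated()].tolist()
            raise FormatError(f"duplicate gene ID(s) {dup}")
        if len(set(self.columns)) != len(self.columns):
            raise FormatError("duplicate (strain, replicate) column")
        if self.values.size and np.isinf(self.values).any():
            raise FormatError("non-finite (infinite) expression value")

    @property
    def strain_numbers(self) -> list[int]:
        """Distinct strain numbers in column order of first appearance."""
        out: list[int] = []
        seen: set[int] = set()
        for s, _ in self.columns:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out

    def replicate_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for s, _ in self.columns:
            counts[s] = counts.get(s, 0) + 1
        return counts

    def subset_strains(self, strains: Iterable[int]) -> "ExpressionMatrix":
        keep = set(strains)
        idx = [i for i, (s, _) in enumerate(self.columns) if s in keep]
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.columns[i] for i in idx],
            self.values[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["strain", "replicate"])
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene"),
                            columns=cols)


def _detect_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def _parse_size(token: str, row_no: int) -> float:
    cleaned = token.strip().replace(",", "")
    try:
        return float(cleaned)
    except ValueError:
        raise FormatError(f"non-numeric eye size {token.strip()!r} on row {row_no}") from None


def read_phenotype_table(path: str | Path, dialect: str | None = None) -> PhenotypeTable:
    """Read a two-column strain / mean-eye-size table.

    The delimiter is auto-detected (tab or comma) from the first line unless
    ``dialect`` forces one. Thousands separators inside the size column are
    stripped, which also copes with comma-delimited rows like
    ``RAL021, 19,976.8``: the line is split once on the first delimiter and
    the remainder is treated as the (possibly comma-grouped) number.
    """
    path = Path(path)
    strains: list[int] = []
    sizes: list[float] = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return PhenotypeTable([], np.empty(0))
    delim = dialect or _detect_delimiter(lines[0])
    start = 0
    first = lines[0].split(delim, 1)
    if len(first) == 2:
        try:
            _parse_size(first[1], 1)
        except FormatError:
            start = 1  # header row
    for row_no, ln in enumerate(lines[start:], start=start + 1):
        parts = ln.split(delim, 1)
        if len(parts) != 2:
            raise FormatError(f"expected two columns on row {row_no}: {ln!r}")
        strains.append(canonical_strain_number(parts[0]))
        sizes.append(_parse_size(parts[1], row_no))
    return PhenotypeTable(strains, np.asarray(sizes))


def _parse_line_column(name: str) -> tuple[int, int]:
    m = _LINE_RE.match(name.strip())
    if not m or m.group(2) is None:
        raise FormatError(f"malformed expression column name {name!r} "
                          "(expected line_<N>:<rep>)")
    return int(m.group(1)), int(m.group(2))


def read_expression_matrix(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a wide gene x ``line_<N>:<rep>`` expression matrix."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return ExpressionMatrix([], [], np.empty((0, 0)))
    delim = dialect or _detect_delimiter(lines[0])
    header = lines[0].split(delim)
    columns = [_parse_line_column(c) for c in header[1:]]
    n_cols = len(columns)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for row_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split(delim)
        if len(parts) != n_cols + 1:
            raise FormatError(
                f"ragged row {row_no}: expected {n_cols + 1} fields, got {len(parts)}")
        gene_ids.append(parts[0].strip())
        vals = []
        for tok in parts[1:]:
            tok = tok.strip()
            if tok == "" or tok.upper() in {"NA", "NAN"}:
                vals.append(np.nan)
            else:
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise FormatError(
                        f"non-numeric expression value {tok!r} on row {row_no}") from None
        rows.append(vals)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, n_cols))
    return ExpressionMatrix(gene_ids, columns, values)


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("Strain\tMean_Eye_Size\n")
        for s, v in zip(table.strain_ids, table.eye_sizes):
            fh.write(f"{ral_form(s)}\t{float(v)!r}\n")


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        header = ["Gene"] + [line_form(s, r) for s, r in expr.columns]
        fh.write("\t".join(header) + "\n")
        for gid, row in zip(expr.gene_ids, expr.values):
            toks = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write("\t".join([gid] + toks) + "\n")


# --- candidate table -------------------------------------------------------

_CAND_COLUMNS = [
    "gene", "cluster",
    "pearson_r", "pearson_p", "pearson_rank",
    "kendall_tau", "kendall_p", "kendall_rank",
    "spearman_r", "spearman_p", "spearman_rank",
    "in_intersection",
]


def write_candidate_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a candidate table (one row per gene per cluster of origin) as TSV.

    Floats are written at full precision so a read-back round-trips exactly.
    """
    path = Path(path)
    df = table.copy()
    missing = [c for c in _CAND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table missing column(s) {missing}")
    df = df[_CAND_COLUMNS]
    with path.open("w") as fh:
        fh.write("\t".join(_CAND_COLUMNS) + "\n")
        for _, row in df.iterrows():
            toks = []
            for col in _CAND_COLUMNS:
                v = row[col]
                if col in ("gene",):
                    toks.append(str(v))
                elif col in ("cluster",) or col.endswith("_rank"):
                    toks.append("" if pd.isna(v) else str(int(v)))
                elif col == "in_intersection":
                    toks.append("1" if bool(v) else "0")
                else:
                    toks.append("" if pd.isna(v) else repr(float(v)))
            fh.write("\t".join(toks) + "\n")


def read_candidate_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str},
                     float_precision="round_trip")
    if list(df.columns) != _CAND_COLUMNS:
        raise FormatError(f"unexpected candidate table header in {path}")
    df["in_intersection"] = df["in_intersection"].astype(bool)
    for col in _CAND_COLUMNS:
        if col.endswith("_rank") or col == "cluster":
            df[col] = df[col].astype("Int64")
    return df


def write_cluster_assignments(assignments: dict[int, int], path: str | Path) -> None:
    """Write strain -> cluster label as a two-column TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("strain\tcluster\n")
        for s, c in assignments.items():
            fh.write(f"{ral_form(s)}\t{c}\n")


def write_run_manifest(manifest: dict, path: str | Path) -> None:
    """Persist run parameters, seeds, thresholds and filter counts as JSON."""
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(manifest, indent=2, default=_default) + "\n")
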