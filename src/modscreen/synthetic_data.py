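"""Synthetic strain panels with known ground truth.

The generator emulates the shape of a DGRP-style screen: a two-column strain /
eye-size table, a wide gene x ``line_<N>:<rep>`` expression matrix with two
replicates per strain, partial strain overlap between the two files, and
strains with a missing replicate. Ground truth (planted modifier genes, strain
group memberships, filtered-strain bookkeeping) is written alongside.

Generative model (see docs/methods.md for the rationale):

* Strains fall into ``n_blocks`` expression blocks. Block 0 skews toward large
  eye sizes, block 1 toward small ones, the rest sit mid-range; the spans
  overlap so eye size varies substantially inside every block.
* Each block has a disjoint set of marker genes shifted by a constant in that
  block only, giving K-Means a recoverable strain partition.
* Planted modifier genes are linear in eye size with Gaussian strain noise,
  calibrated so the population expression-phenotype correlation equals
  ``effect``.
* Background genes sit at a flat per-gene baseline plus replicate noise, and
  each carries one large aberrant strain measurement per block (an on/off-
  scale artifact). These aberrations are what real panels throw at a
  correlation screen, and they are exactly the pathology the three-method
  intersection is meant to reject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (ExpressionMatrix, PhenotypeTable, line_form, ral_form,
                         write_expression_matrix, write_phenotype_table)

__all__ = ["SyntheticConfig", "SyntheticPanel", "generate", "write_panel"]

# Eye-size span of each block, as fractions of the configured range.
# Overlapping spans keep within-block eye-size variance high (so planted
# correlations survive conditioning on a block) while still concentrating
# the top and bottom quadrant in blocks 0 and 1 respectively.
_HIGH_SPAN = (0.40, 1.00)
_LOW_SPAN = (0.00, 0.60)
_MID_SPAN = (0.25, 0.75)


@dataclass
class SyntheticConfig:
    """Panel shape and noise model; defaults are the reference study design."""

    n_strains: int = 200            # fully usable strains (post-filter cohort)
    n_genes: int = 2000
    n_planted: int = 10             # phenotype-correlated modifier genes
    effect: float = 0.6             # population |r| of planted genes, in (0, 1]
    n_blocks: int = 3               # expression blocks = plantable clusters
    eye_size_range: tuple[float, float] = (14254.6, 27349.11)  # pixels x 10^3
    replicate_noise_sd: float = 0.1
    strain_noise_sd: float = 0.4    # planted-gene biological strain noise
    marker_genes_per_block: int = 80
    marker_shift: float = 3.0       # log2-scale block shift of marker genes
    aberration_amplitude: tuple[float, float] = (10.0, 14.0)  # log2 units
    aberrations_per_block: int = 1  # aberrant strains per background gene per block
    baseline_range: tuple[float, float] = (3.0, 12.0)
    missing_replicate_strains: int | Sequence[int] = 1
    extra_strains_per_file: tuple[int, int] = (3, 3)  # (pheno-only, expr-only)
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if not (0 < self.effect <= 1):
            raise ValueError("effect must lie in (0, 1]")
        if self.eye_size_range[0] >= self.eye_size_range[1]:
            raise ValueError("eye_size_range must satisfy min < max")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_strains < self.n_blocks:
            raise ValueError("need at least one strain per block")
        n_marked = self.n_planted + self.n_blocks * self.marker_genes_per_block
        if n_marked > self.n_genes:
            raise ValueError(
                f"planted + marker genes ({n_marked}) exceed n_genes ({self.n_genes})")


@dataclass
class SyntheticPanel:
    phenotypes: PhenotypeTable
    expression: ExpressionMatrix
    truth: dict = field(default_factory=dict)


def _block_span(block: int) -> tuple[float, float]:
    if block == 0:
        return _HIGH_SPAN
    if block == 1:
        return _LOW_SPAN
    return _MID_SPAN


def generate(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticPanel:
    """Draw a complete panel; deterministic given the config (and its seed)."""
    cfg = config or SyntheticConfig()
    if seed is not None:
        cfg = SyntheticConfig(**{**asdict(cfg), "seed": seed})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n, g = cfg.n_strains, cfg.n_genes
    if isinstance(cfg.missing_replicate_strains, (int, np.integer)):
        n_missing = int(cfg.missing_replicate_strains)
        explicit_missing = None
    else:
        n_missing = len(cfg.missing_replicate_strains)
        explicit_missing = [int(s) for s in cfg.missing_replicate_strains]
    n_pheno_extra, n_expr_extra = cfg.extra_strains_per_file
    n_total = n + n_missing + n_pheno_extra + n_expr_extra

    # distinct strain numbers in the DGRP-like 21..999 band
    pool = rng.choice(np.arange(21, 1000), size=n_total, replace=False)
    core = sorted(int(s) for s in pool[:n])
    if explicit_missing is not None:
        missing = explicit_missing
    else:
        missing = sorted(int(s) for s in pool[n:n + n_missing])
    pheno_only = sorted(int(s) for s in pool[n + n_missing:n + n_missing + n_pheno_extra])
    expr_only = sorted(int(s) for s in pool[n + n_missing + n_pheno_extra:])

    # block memberships for every strain that appears in the expression file
    expr_strains = core + missing + expr_only
    blocks = {s: int(b) for s, b in
              zip(expr_strains, rng.integers(0, cfg.n_blocks, len(expr_strains)))}
    # guarantee every block is populated within the core cohort
    sizes = np.full(cfg.n_blocks, n // cfg.n_blocks)
    sizes[: n % cfg.n_blocks] += 1
    core_blocks = np.repeat(np.arange(cfg.n_blocks), sizes)
    rng.shuffle(core_blocks)
    for s, b in zip(core, core_blocks):
        blocks[s] = int(b)

    # eye sizes: block-dependent span of the configured range
    mn, mx = cfg.eye_size_range
    rngspan = mx - mn
    pheno_strains = core + missing + pheno_only
    eye = {}
    for s in pheno_strains:
        b = blocks.get(s, rng.integers(0, cfg.n_blocks))
        lo, hi = (0.0, 1.0) if cfg.n_blocks == 1 else _block_span(int(b))
        eye[s] = mn + rngspan * rng.uniform(lo, hi)

    # gene identities
    gene_ids = []
    for i in range(g):
        prefix = "FBgn" if i % 5 else "XLOC"   # exercise both ID conventions
        gene_ids.append(f"{prefix}{7000000 + i:07d}" if prefix == "FBgn"
                        else f"XLOC_{7000000 + i:07d}")
    planted_genes = gene_ids[: cfg.n_planted]
    marker_slices = {
        b: gene_ids[cfg.n_planted + b * cfg.marker_genes_per_block:
                    cfg.n_planted + (b + 1) * cfg.marker_genes_per_block]
        for b in range(cfg.n_blocks)
    }

    baseline = rng.uniform(*cfg.baseline_range, size=g)

    # strain-level expression (before replicates), strains in expr file order
    S = len(expr_strains)
    X = np.tile(baseline[:, None], (1, S))
    col_block = np.array([blocks[s] for s in expr_strains])

    # marker shifts
    for b in range(cfg.n_blocks):
        gi = np.arange(cfg.n_planted + b * cfg.marker_genes_per_block,
                       cfg.n_planted + (b + 1) * cfg.marker_genes_per_block)
        X[np.ix_(gi, np.where(col_block == b)[0])] += cfg.marker_shift

    # planted genes: linear in eye size, Gaussian strain noise, slope
    # calibrated so that corr(replicate-averaged expression, eye size) at the
    # population level equals `effect`
    eye_vec = np.array([eye.get(s, mn + 0.5 * rngspan) for s in expr_strains])
    z = (eye_vec - eye_vec.mean()) / eye_vec.std()
    noise_var = cfg.strain_noise_sd**2 + cfg.replicate_noise_sd**2 / 2.0
    if cfg.effect >= 1.0:
        # noiseless limit: exactly linear in eye size at the strain level
        beta, planted_sd = 1.0, 0.0
    else:
        beta = float(np.sqrt(noise_var * cfg.effect**2 / (1 - cfg.effect**2)))
        planted_sd = cfg.strain_noise_sd
    if cfg.n_planted:
        signs = rng.choice([-1.0, 1.0], size=cfg.n_planted)
        X[: cfg.n_planted] += signs[:, None] * beta * z[None, :]
        if planted_sd > 0:
            X[: cfg.n_planted] += rng.normal(0, planted_sd, (cfg.n_planted, S))

    # background aberrations: per gene, one aberrant strain per block
    bg = np.arange(cfg.n_planted, g)
    amp_lo, amp_hi = cfg.aberration_amplitude
    for b in range(cfg.n_blocks):
        cols = np.where(col_block == b)[0]
        if not len(cols):
            continue
        for _ in range(cfg.aberrations_per_block):
            pick = rng.choice(cols, size=len(bg))
            amp = rng.uniform(amp_lo, amp_hi, len(bg)) * rng.choice([-1.0, 1.0], len(bg))
            X[bg, pick] += amp

    # replicates with independent technical noise; one configured strain set
    # loses its first replicate
    columns: list[tuple[int, int]] = []
    cols_data: list[np.ndarray] = []
    for j, s in enumerate(expr_strains):
        reps = (2,) if s in set(missing) else (1, 2)
        for r in reps:
            columns.append((s, r))
            cols_data.append(X[:, j] + rng.normal(0, cfg.replicate_noise_sd, g))
    values = np.column_stack(cols_data) if cols_data else np.empty((g, 0))

    phenotypes = PhenotypeTable(pheno_strains,
                                np.array([eye[s] for s in pheno_strains]))
    expression = ExpressionMatrix(gene_ids, columns, values)

    truth = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "planted_genes": planted_genes,
        "planted_signs": ([] if not cfg.n_planted else
                          [int(v) for v in signs]),
        "marker_genes": {str(b): gl for b, gl in marker_slices.items()},
        "blocks": {ral_form(s): blocks[s] for s in expr_strains},
        "core_strains": [ral_form(s) for s in core],
        "missing_replicate_strains": [ral_form(s) for s in missing],
        "phenotype_only_strains": [ral_form(s) for s in pheno_only],
        "expression_only_strains": [ral_form(s) for s in expr_only],
        "high_block": 0 if cfg.n_blocks > 1 else None,
        "low_block": 1 if cfg.n_blocks > 1 else None,
    }
    return SyntheticPanel(phenotypes=phenotypes, expression=expression, truth=truth)


def write_panel(panel: SyntheticPanel, outdir: str | Path) -> dict[str, Path]:
    """Write phenotype.tsv, expression.tsv and truth.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotype": outdir / "phenotype.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    write_phenotype_table(panel.phenotypes, paths["phenotype"])
    write_expression_matrix(panel.expression, paths["expression"])
    paths["truth"].write_text(json.dumps(panel.truth, indent=2) + "\n")
    return paths
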