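# Methods

## The screen

The package identifies candidate modifier genes of a quantitative degeneration
phenotype (eye size in a fly model of retinitis pigmentosa) from two inputs: a
strain → mean-eye-size table and a wide gene × replicate expression matrix
over a panel of inbred strains. The screen makes three assumptions worth
stating explicitly:

1. **Expression profiles carry strain-group structure.** K-Means over the raw
   replicate-averaged expression matrix (squared Euclidean distance, all genes
   weighted equally, no normalization or log transform beyond what the input
   already is, no dimensionality reduction) can partition strains into
   coherent groups. The absence of any rescaling is deliberate and affects
   cluster geometry: genes with large absolute spread dominate distances.
2. **Phenotype extremes concentrate in particular expression groups.** The
   eye-size range is cut into four quadrants; the cluster holding the most
   strains strictly above `max − range/4` (resp. strictly below
   `min + range/4`) is declared the high (resp. low) outlier cluster.
   Comparisons are strict; argmax ties or an empty side abort with an error
   rather than guessing.
3. **Within an outlier cluster, a modifier's expression tracks eye size
   monotonically.** Per-gene association is measured three ways — Pearson's r
   (linear), Kendall's τ and Spearman's r_s (ordinal) — and only genes ranked
   in the top 20 by |coefficient| with p < 0.05 under *all three* are called
   candidates. The intersection is the robustness device: the three
   statistics have very different sensitivities to outlying values, so genes
   that owe their apparent association to a few aberrant measurements fail at
   least one test.

## Statistical details

- **Pearson**: r = Σ z_x z_y/(n−1) with sample-sd (ddof 1) standardization;
  two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df. Constant input is an
  error at the single-vector level; in the per-gene driver a constant gene is
  reported with a NaN coefficient and a `constant` flag instead.
- **Kendall**: pair counts by explicit O(n²) sign enumeration. `tau_a` is
  (n_c−n_d)/n₀ with n₀ = n(n−1)/2; the default `tau_b` divides by
  √((n₀−T_x)(n₀−T_y)). p comes from the normal approximation to
  S = n_c − n_d, with the standard tie adjustment to var(S) under `tau_b`; no
  continuity correction. An exact permutation p would differ at very small n,
  which the screen does not target.
- **Spearman**: average ranks (ties share the mean rank), then the Pearson
  formula on ranks; p via the same t approximation.
- **Significance** is a per-test p < α (default 0.05) cutoff with no
  multiple-testing correction. That is a screening choice, not an inferential
  one — the output is a shortlist for experimental validation, and the
  nominal cutoff is recorded in the run manifest. Ranking filters first and
  truncates second; a `rank_then_filter` flag implements the other order.
- **Ranking ties** in |coefficient| break by ascending p, then gene ID, so
  runs are deterministic.

A note on τ variants: in the published worked example for this screen the
printed pair counts (n_c = 6718, n_d = 7817, n₀ = 14 535) give
(n_c−n_d)/n₀ = −0.0756 under the tau_a formula, while the printed coefficient
is −0.090 — consistent with a tie-corrected library value. This package
defaults to `tau_b` and keeps `tau_a` available; the discrepancy is noted
here rather than resolved.

## K-Means

Lloyd's iteration with initialization by k distinct strains drawn uniformly
without replacement, run from 10 seeded restarts; the restart with minimum
within-cluster sum of squares (WSS) is kept. Convergence is "no strain
reassigned". An emptied cluster is repaired by re-seeding its centroid at the
point farthest from its current centroid, which cannot increase the
objective; the WSS trace is recorded and is non-increasing within a run.
Everything is deterministic given (data, k, seed, restarts).

k defaults to 6 for real panels: silhouette sweeps on ~170 strains tend to
recommend k = 2, which cannot separate a high- and a low-phenotype grouping
from the bulk, so the sweep is reported as advisory only. For synthetic
panels the right k is the generator's block count (3 by default), and the
recovery experiments use k = 3. The 2-D PCA embedding exists solely for
plots; clustering and selection never touch it.

Zero-variance genes are retained (they contribute nothing to distances) and
flagged in the manifest rather than dropped.

## The synthetic panel generator

The generator emulates the *shape* of a DGRP-style screen — `line_<N>:<rep>`
replicate columns, `RAL`-style phenotype rows, partial overlap between the two
files (default 3 strains exclusive to each), one strain with a missing first
replicate, FBgn/XLOC gene-ID conventions, eye sizes spanning the published
range (14 254.6–27 349.11 pixels × 10³) — with ground truth recorded in
`truth.json`.

Generative model, with defaults:

- **Blocks.** Strains split evenly into `n_blocks = 3` expression blocks.
  Block 0 draws eye sizes uniformly from the top 60% of the range, block 1
  from the bottom 60%, mid blocks from the middle 50%. The overlap keeps
  substantial eye-size variance *within* each block (a planted correlation
  survives conditioning on a block), while the top and bottom quadrant are
  still dominated by blocks 0 and 1, so outlier-cluster identification is
  well defined by construction. The published eye-size distribution is more
  nearly unimodal; the mixture is a testability device.
- **Markers.** Each block has 80 marker genes shifted by +3 (log2-scale
  units) in that block only. This makes the block partition the clear WSS
  optimum, so K-Means recovers it.
- **Planted modifiers** (`n_planted = 10`, `effect = 0.6`): expression =
  baseline ± β·z(eye size) + N(0, σ), with σ = 0.4 and β =
  √((σ² + σ_rep²/2)·effect²/(1−effect²)) so the population correlation of the
  replicate-averaged value with eye size is `effect`. Signs are random.
  `effect = 1` is special-cased as exactly linear (the calibration formula
  diverges), giving |r| = 1 when replicate noise is also zero.
- **Background genes** sit at a flat per-gene baseline (uniform 3–12) with
  replicate-level technical noise (sd 0.1 per replicate) and **one aberrant
  strain measurement per block**: a ±10–14 log2-unit shift (an on/off-scale
  artifact — a large-effect expression polymorphism, CNV or technical
  failure) at one strain per block, placed stratified so every gene has
  exactly one aberration inside any block-shaped cluster. This is the
  pathology the three-method intersection exists to reject: a single
  aberrant point caps a background gene's within-cluster Pearson |r| at
  max|z_x|/√(n−1) ≈ 0.21 for ~67 uniform-phenotype strains — below the
  p < 0.05 threshold (≈ 0.24) — while the rank statistics see one extreme
  rank plus technical noise. The Pearson and rank-method null extremes are
  therefore nearly disjoint, and the intersection table stays clean: on the
  default panel the pipeline recovers ~10/10 planted modifiers with ~0–2
  background genes.
- Background genes carry essentially no Gaussian strain-level biological
  variance beyond the block and aberration terms. This is the deliberately
  stylized part of the model: it makes the screen's false-positive behaviour
  attributable to the aberration mechanism alone.

**What passing tests do and do not show.** The recovery experiments show that
the pipeline's plumbing, selection logic and intersection behave correctly
under a favourable but not trivial noise model. Real panels have correlated
gene–gene structure, eQTL architecture, unequal residual variances and
Gaussian biological strain noise on every gene; under a plain iid Gaussian
background the three methods' lucky-null extremes largely coincide, and a
top-20 intersection would admit several spurious genes per cluster. Passing
the synthetic recovery test therefore does not bound the false-positive rate
on real data — it validates the machinery, not the biology.

**Type-I calibration** is performed against the analytic null the tests
assume: an aberration-free, single-block, no-planting panel (and,
equivalently, plain Gaussian matrices in the unit tests), where each method
flags ≈ 5% of genes at α = 0.05 (30 strains × 2 000 genes). Under the
default aberration model Pearson's test is conservative by construction;
that is documented behaviour, not a calibration target.

## Numerical and interface choices

- Coefficients are clamped to [−1, 1] after the dot product (guarding 1-ulp
  overshoot); oracle tests require 1e−12 agreement with brute-force
  implementations.
- Table round-trips write floats with `repr` and read with pandas
  `float_precision="round_trip"`, so write→read is bit-exact.
- Strain IDs are canonicalized to integers; `RAL021`, `line_21` and
  `line_21:1` are the same strain. The phenotype reader splits each row once
  on the detected delimiter, so comma-delimited rows with thousands
  separators (`RAL021, 19,976.8`) parse correctly.
- Replicate counts are not limited to 2; `required_replicates` is
  configurable and a lenient `allow_partial_replicates` mode averages
  whatever replicates exist. Missing cells always remove the affected strain
  (no imputation).
- The strict strain-filtering default mirrors the treatment of strain 513 in
  the reference data (dropped entirely for a missing replicate).
- Problem sizes in the test-suite and acceptance experiments (e.g. 90–200
  strains, 400–2 000 genes, 100 toy K-Means instances) were chosen as the
  smallest panels at which each phenomenon under test is unambiguous;
  scaled-down panels strengthen the block markers (shift 6 instead of 3) so
  the clustering optimum stays as decisive as at full scale.

## Known limitations

- No batch correction, normalization or variance filtering; inputs are taken
  as published.
- No FDR control; the candidate list is a screen, not a hypothesis test.
- Alternative clusterers (Gaussian mixtures, density-based methods) are out
  of scope.
- The real-data outcomes of the reference screen (171 intersecting strains,
  cluster sizes 38/37, the specific candidate genes) depend on the external
  eye-size and DGRP files and on an unrecorded RNG state, and are not
  reproducible from this repository; the procedure, not those numbers, is
  what the tests pin down.
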