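# modscreen

**Cluster-based expression–phenotype screening for candidate modifier genes
in inbred strain panels.**

Inherited degenerative diseases such as retinitis pigmentosa (RP) vary widely
in severity between individuals carrying the same causal mutation. In the
*Drosophila* Rh1^G69D model of RP, that variation can be read out
quantitatively: eye size (pixels × 10³, measured from standardized images)
shrinks as retinal degeneration worsens. Combining per-strain eye sizes with a
panel-wide expression matrix (DGRP-style: ~18k genes × ~200 inbred strains ×
2 replicates) lets one screen for **modifier genes** — genes whose expression
level tracks the severity of degeneration.

`modscreen` implements that screen:

1. **Preprocess** — keep strains present in both tables, drop strains with an
   incomplete replicate pair (e.g. `line_513:2` without `line_513:1`), and
   average each strain's replicates into one expression value per gene.
2. **Cluster** — K-Means (Lloyd's algorithm, squared Euclidean distance over
   all genes, best of 10 seeded restarts by within-cluster sum of squares)
   groups strains by expression profile. Silhouette widths for k = 2..8 are
   reported as advisory; the screening default is k = 6.
3. **Outlier clusters** — the eye-size range [min, max] is split into four
   quadrants: upper threshold = max − (max−min)/4, lower = min + (max−min)/4.
   The cluster with the most strains strictly above the upper threshold is the
   high-eye-size outlier cluster; symmetrically for the lower threshold.
4. **Correlate** — within each outlier cluster, every gene's averaged
   expression y is correlated with eye size x using three coefficients:

   - Pearson  r = Σ z_x z_y / (n−1)
   - Kendall  τ = (n_c − n_d) / n₀,  n₀ = n(n−1)/2 (tau_a; the tie-corrected
     tau_b is the default)
   - Spearman r_s = Pearson applied to the rank vectors

   with two-sided p-values (t approximation for r and r_s, normal
   approximation to the concordance statistic for τ) and a plain p < 0.05
   cutoff (no multiple-testing correction — deliberately, and recorded in the
   run manifest).
5. **Candidates** — per cluster and per method, the significant genes with the
   top-20 absolute coefficients are kept; genes shared by **all three**
   methods form the candidate-modifier table (unioned over the two outlier
   clusters, keeping both sets of statistics for genes selected twice).

A synthetic-panel generator (`modscreen simulate`) reproduces the full data
shape — replicate column naming, partial strain overlap between files, missing
replicates, planted phenotype-correlated genes, and planted cluster structure
— so the whole pipeline is testable end to end with known ground truth.

## Worked example

Simulate the default panel (200 usable strains, 2 000 genes, 10 planted
modifiers with population correlation 0.6) and run the screen with k = 3
clusters (the generator plants three expression blocks):

```bash
modscreen simulate --seed 1 --out panel
modscreen run --pheno panel/phenotype.tsv --expr panel/expression.tsv \
              --k 3 --seed 1 --out screen
```

Output:

```
50 ranked genes; 12 in the three-method intersection:
  FBgn7000001
  FBgn7000002
  ...
  XLOC_7000005
  FBgn7000008
  FBgn7000424
```

`panel/truth.json` lists the 10 planted modifiers; in this run the
intersection table recovers **all 10** (e.g. `FBgn7000001`, `XLOC_7000000`)
plus 2 background genes. `screen/candidates.tsv` holds every ranked gene with
per-method coefficient, p-value and rank, its cluster of origin, and the
intersection flag:

```
gene         cluster  pearson_r  pearson_p  pearson_rank  ...  in_intersection
FBgn7000001  3        0.499      1.7e-05    5             ...  1
```

`screen/manifest.json` records every parameter, seed, threshold, cluster size
and filtered strain, so a rerun with the same inputs and seed is
byte-identical.

The same screen runs unchanged on real Rh1^G69D eye-size and DGRP expression
files in the formats above (`Strain<TAB>Mean_Eye_Size` with optional thousands
separators; `Gene<TAB>line_<N>:1<TAB>line_<N>:2 ...`).

## Layout

```
src/modscreen/
  io_formats.py     # table dialects, strain-ID canonicalization, TSV/JSON output
  preprocess.py     # strain intersection, replicate filtering and averaging
  clustering.py     # Lloyd K-Means, silhouette, PCA embedding, thresholds
  correlation.py    # Pearson / Kendall / Spearman with p-values
  candidates.py     # top-k ranking, three-method intersection, pipeline driver
  synthetic_data.py # ground-truth panel generator
  cli.py, plots.py
```

See `docs/methods.md` for the model, parameter choices and limitations.
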