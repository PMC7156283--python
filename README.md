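# clonolink

Joint analysis of paired single-cell RNA-seq and single-cell TCR-seq data
from regulatory T cells (Tregs), built for studies that ask how a
Treg-expanding treatment (here an IL-2 mutein, "IL2M", vs isotype control,
"Iso") reshapes the Treg landscape across tissues — and whether clonally
related cells end up in different transcriptional states or tissues.

The package is a Python library plus a thin `clonolink` CLI. It covers:

- **QC and normalization** of sparse UMI count matrices (MatrixMarket
  triplet + per-cell metadata): cells with < 500 or > 8,000 detected genes
  are removed; counts are library-size scaled to 10⁴ and log1p-transformed.
- **Cell-state classification**: PCA → kNN graph → Leiden community
  detection at resolution 0.6 (with a 0.1–1.0 resolution sweep), labels
  C1…Ck by decreasing size. Marker genes per state by two-sided Wilcoxon
  rank-sum test with Benjamini–Hochberg correction; *hallmark* genes are the
  top 10 markers with adjusted *p* < 0.01, average log₂FC > 0.3 and
  significant enrichment in fewer than half of all states (mitochondrial and
  pseudogenes excluded).
- **Clonotypes**: a cell enters the TCR analysis only with exactly one
  productive TRA and one productive TRB contig; the clonotype key is
  (Vα, Jα, CDR3α, Vβ, Jβ, CDR3β) with exact identity (nucleotide CDR3 by
  default, alleles stripped). TCR and transcriptome are merged on the cell
  barcode.
- **Clonal-family statistics**: a clonal family (CF) is a clonotype seen in
  ≥ 2 cells. For each treatment condition the package computes the
  *cell-state axis* table — for every unordered state pair {A, B} the number
  of same-family cell pairs spanning A and B, divided by the total number of
  clonotypes — chord-diagram edge lists, inter- vs intra-tissue CF
  percentages, the CF-membership × treatment Fisher exact test, and the
  expansion summary (percent change in CF cells and in recovered TCR cells).
- **Correlation null**: Pearson correlation of log-normalized expression
  (top 2,000 variable genes) for every same-clonotype cell pair, compared
  with up to 10,000 randomly sampled non-co-familial pairs by a two-tailed
  Welch *t* test, optionally at equal group sizes.
- **Synthetic data**: a negative-binomial generator with planted states,
  tissue/treatment compositions, clonal families and a tunable shared
  within-clonotype program, so every stage is testable against ground truth.

## Worked example

`python examples/03_clonotypes_and_sharing.py` generates a 3,600-cell
synthetic dataset, assigns clonotypes and prints:

```
3600 paired cells -> 3394 clonotypes, 3600 linked
           n_cells  n_clonotypes  n_CFs  n_CF_cells
treatment
IL2M          1838          1704     79         213
Iso           1762          1690     39         111
CF-cell change IL2M vs Iso: +92% (TCR cells +4%)
Fisher p (CF membership x treatment): 2.61e-08
axis C2-C2: 25 pairs (1.7% of clonotypes)
axis C6-C6: 24 pairs (1.6% of clonotypes)
axis C4-C4: 22 pairs (1.5% of clonotypes)
```

The CF-cell count nearly doubles under IL2M while the number of recovered
TCR cells barely moves — the signature of treatment-driven clonal expansion
rather than deeper sampling. The axis lines read: of all clonotypes in the
IL2M arm, 1.7% contribute a same-clonotype cell pair in which both cells sit
in state C2, and so on; axes linking two *different* states indicate that
one progenitor's descendants occupy distinct transcriptional states.

The other examples cover QC (`01`), clustering and hallmark-gene selection
(`02`), and the same-clonotype correlation null (`04`).

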