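# Methods

## Scope and data model

The package analyzes paired single-cell measurements of regulatory T cells:
a sparse cells × genes UMI count matrix with per-cell metadata (tissue ∈
{spleen, lung, gut}, treatment ∈ {Iso, IL2M}, replicate), and a 10x-style
TCR contig annotation table (barcode, chain, V/J calls, CDR3 nt/aa,
productive flag). The two modalities are joined on the cell barcode. All
statistics treat the *clonotype* — the exact rearranged TCRαβ identity — as
the unit of lineage, and a *clonal family* (CF) as a clonotype observed in
at least two linked cells.

## Quality control and normalization

Cells with fewer than 500 detected genes (low-quality transcriptomes) or
more than 8,000 (putative doublets) are removed; both cuts are strict, so
cells at exactly 500 or 8,000 are retained. "Detected" means nonzero count.
The filter is applied globally, not per replicate. Expression is
library-size normalized to 10,000 counts per cell and log1p-transformed;
the scale is configurable. An all-zero cell passes through as zeros with a
warning rather than an error.

## Cell-state classification

Cells are embedded with PCA (30 components, randomized solver with fixed
seed), joined into an undirected k-nearest-neighbor graph (k = 15,
Euclidean distance in PC space), and partitioned with the Leiden algorithm
under the RBConfiguration quality function. Leiden is used as the modern,
seedable refinement of Louvain-style modularity clustering; the resolution
parameter defaults to 0.6 and a sweep over 0.1–1.0 in steps of 0.1 is
provided, reporting per resolution the state count and the smallest state's
size and top markers — the information one needs to decide whether a finer
resolution reveals a biologically coherent population. Labels are C1…Ck in
decreasing cluster size. A matrix with no variance at all (every cell
identical) is assigned a single state directly: a kNN graph on coincident
points is arbitrary, and community detection on it would be meaningless.

The number of states found is *not* guaranteed to be monotone in the
resolution; empirically it is on the data shapes generated here, and the
test suite checks it as a seeded property, not a theorem.

### Marker and hallmark genes

Differential expression of one state versus all other cells uses the
two-sided Wilcoxon rank-sum (Mann–Whitney) test — the normal approximation
with tie correction for routine use, exact enumeration available for small
groups — with Benjamini–Hochberg adjustment across genes within each state.
The average log₂ fold change is computed on expm1-backtransformed
normalized means with a pseudocount of 1e-9. A gene whose values are
identical in both groups gets p = 1.

Hallmark genes per state are the top 10 markers (ranked by adjusted p, ties
broken by fold change then name) satisfying adjusted p < 0.01 and average
log₂FC > 0.3, excluding genes significantly *enriched* (adjusted p < 0.01
with positive fold change) in at least half of all states, and excluding
mitochondrial/pseudogene names by configurable patterns (`mt-*`, `Gm####`,
`*-ps*`, `*Rik` by default). The positive-fold condition in the
promiscuity rule matters: with a two-sided test a genuine marker of one
state is also significantly depleted in most others, and counting depletion
would disqualify every real marker. BH adjustment is per state; "top 10"
ranks by adjusted p.

### Composition and batch tests

Treatment shifts in state composition are tested per (tissue, state):
frequency = state cells / (tissue, treatment, replicate) cells, compared
across replicates by Welch's unequal-variance t (two-tailed). When both
arms have zero variance the limit is reported instead of NaN: p = 1 for
equal means, p = 0 with a `degenerate` flag otherwise. With fewer than two
replicates per arm only frequencies are reported. Batch effects are tested
per state for each pair of replicates with a two-sided Fisher exact test on
the 2×2 in-state × batch table.

## Clonotypes

A cell is admitted to the clonotype analysis iff it has exactly one
productive TRA and exactly one productive TRB contig. Extra non-productive
contigs do not disqualify a cell (the rule counts productive chains);
a second productive contig of either chain does. The clonotype key is
(Vα, Jα, CDR3α, Vβ, Jβ, CDR3β) under exact equality; CDR3 identity is at
the nucleotide level by default with an amino-acid mode available, and
allele suffixes (`*01`) are stripped from gene calls before comparison
(configurable). Clonotype ids are assigned in sorted-key order, making the
partition invariant to input order.

## Clonal-family statistics

**Cell-state axes.** Within an analysis subset (one treatment; spleen and
lung cells by default, since that is the subset in which state-sharing
networks are interpretable when gut TCR recovery is low), every unordered
pair of same-family cells contributes one count to the unordered state pair
of its members — same-state pairs (C4–C4) included. The axis frequency
divides the count by the total number of clonotypes in the subset,
singletons included; a `cf_pairs` denominator (fraction of all same-family
pairs) is available as an alternative since the normalization is a
reporting choice. The identity Σ axis counts = Σ_CF C(size, 2) holds by
construction and is asserted in tests.

**Chord links.** Every same-family pair becomes one edge annotated
intra-⟨tissue⟩ or inter-tissue — the edge list behind circular chord plots.

**Tissue sharing.** A CF is inter-tissue if its members span ≥ 2 distinct
tissues, intra-tissue otherwise; percentages are relative to all clonotypes
in the treatment arm. Per class, a 2×2 Fisher exact test (class CFs vs
other clonotypes × treatment) tests the treatment effect.

**Expansion.** Per arm: linked TCR cells, clonotypes, CFs and CF cells,
with IL2M-vs-Iso percent changes ((after − before)/before × 100) kept
unrounded and displayed rounded. The CF-membership × treatment association
is tested with a two-sided Fisher exact test on (cell in CF vs not) ×
treatment.

## Same-clonotype correlation null

One Pearson correlation per unordered same-family cell pair, computed on
log-normalized expression restricted to the 2,000 most variable genes
(configurable; Spearman not needed since ranks change little here — the
metric choice is exposed through the gene subset instead). The null is
built from pairs of linked cells that do not share a family, sampled
uniformly without replacement (exhaustive below the requested size, with a
flag). Groups are compared by a two-tailed Welch t test; the "equal
numbers" mode subsamples the larger group of pair-correlations (not of
cells) to the smaller group's size with a seeded RNG.

**Calibration.** The t test treats pair-correlations as independent
samples. That holds only when (a) same-family cells share no structure
other than the clonotype program being tested, and (b) family pairs are
disjoint in cells. Correlation samples from families of size ≥ 3 share a
cell and are strongly dependent (empirically ≈ 12% type-I at nominal 5%),
and same-family cells necessarily share tissue/state, whose marker programs
correlate transcriptomes regardless of clonal origin (≈ 34% type-I on
default-structured data with no clonotype effect). Under the exchangeable
null — no state signal, size-2 families, zero clonotype effect — the
empirical type-I error is ≈ 4% at 500 replicates. On real data this means
the test demonstrates *association*, not a state-independent clonal
program; a state-matched null would be needed for the stronger claim.

## Synthetic-data generator

The generator emulates the study's structure; defaults are fixed from its
printed summary statistics and are not tuning knobs:

- **Sizes.** 3,600 cells × 1,000 genes by default (a compact panel;
  recovery analyses use 5,000 cells), spleen/lung/gut proportions
  0.54/0.32/0.14, three replicates, two balanced treatment arms.
- **Expression.** Gene base abundances are lognormal (σ = 1), normalized to
  a probability profile. Each of 10 states multiplies its disjoint block of
  20 marker genes by `marker_fold` (default 4) and renormalizes. Counts are
  negative binomial (dispersion r = 2) with cell means = profile × library
  size; library sizes are lognormal with mean 4,000 (σ = 0.35), giving
  ≈ 700 detected genes per cell — UMI-like overdispersion with realistic
  molecules-to-genes ratios for the panel size. Because profiles are
  normalized, the expected molecule count per cell equals the library mean,
  which the tests exploit.
- **Composition.** Per-treatment, per-tissue state probabilities emulate
  the study's landscape: spleen/lung dominated by the resting state plus a
  spleen-specific activated state, gut > 80% activated; the IL2M arm shifts
  mass out of resting into primed/activated states.
- **Clonal families.** 9% of cells are planted into families (the study's
  CF-cell fraction), sizes 2 + Geometric(p = 0.6) (mean ≈ 2.7, matching the
  observed mean family size), 56% of families span ≥ 2 states, 50% span
  ≥ 2 tissues, and 67% of CF cells sit in the IL2M arm (the observed
  share). Families never span treatment or replicate: each (treatment,
  replicate) pair is one animal and a clonotype cannot occur in two
  animals. Family members receive a common multiplicative offset
  (`clonotype_effect`, default 0.3) on a random 50-gene module, renormalized
  so library sizes stay comparable — the weak shared clonal program.
- **TCRs.** One productive TRA + TRB per cell; family members share a
  synthesized (V, J, CDR3) key, all other cells get unique keys. CDR3s are
  random 30–45 nt strings — only identity matters downstream. The noise
  injector adds a second productive chain to an exact fraction of barcodes
  and flips one contig non-productive on a disjoint fraction, to exercise
  the exclusion rules.
- **Determinism.** All randomness descends from one seed through named
  substreams; datasets are bit-reproducible.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, mitochondrial content, realistic V/J germline usage, read-level
noise, per-gene treatment effects, or unequal replicate counts. Passing
tests therefore validate the statistical machinery and its contracts, not
robustness to those artifacts.

## Numerical choices

- Wilcoxon: scipy's tie-corrected normal approximation; exact enumeration
  mode for small tie-free groups (the tests verify it against a brute-force
  rank enumeration for group sizes ≤ 8).
- Fisher exact tests: scipy, verified against hypergeometric enumeration
  for small tables.
- BH: statsmodels `fdr_bh`, per state.
- Degenerate inputs: all-tied genes get p = 1; zero-variance Welch inputs
  get the limiting p with a flag; empty QC results warn rather than raise.
- Percent changes with a zero baseline are NaN, flagged, never infinite.
- Hallmark ties broken by (adjusted p, −log₂FC, gene name) for
  reproducibility.

## Known limitations

- The correlation null is not state-matched (see Calibration above).
- The resolution sweep's monotonicity is empirical, not guaranteed.
- Clustering quality depends on marker strength; at the default fold of 4
  and study scale the planted partition is recovered with ARI > 0.99, but
  weak-signal regimes (fold ≈ 1) are, correctly, unrecoverable.
- The axis-frequency denominator ("all clonotypes") follows the definition
  used for state-sharing networks; comparing axis percentages across
  datasets with very different singleton fractions can mislead, which is
  why the `cf_pairs` denominator is provided.
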