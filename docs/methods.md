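# Methods

## The comparison model

`nhoodcomp` compares the transcriptional landscapes of two species profiled
by scRNA-seq at the granularity of kNN-graph *neighborhoods* rather than
annotated cell types. Independently per species, cells are embedded by PCA
of centered log-normalized expression of the top highly variable genes
(defaults: 2,000 HVGs, 50 components), a k-nearest-neighbor graph is built
in that space (k = 30, Euclidean metric, exact search), and neighborhoods
are defined by sampling index cells at a proportion p = 0.05 of the dataset
and aggregating each index cell with its full symmetrized adjacency set.
Candidate index cells are refined before aggregation: each candidate is
replaced by the cell — among the candidate and its symmetrized graph
neighbors — closest to the mean embedding position of those neighbors, and
refined indices are deduplicated. The refinement prevents oversampling of
dense regions and produces neighborhoods larger than k + 1 (because the
symmetrized adjacency is the *union* of in- and out-edges), which is why
observed mean neighborhood sizes substantially exceed k.

Per neighborhood the mean log-normalized expression profile g_i is computed
over a shared feature set, then rescaled to *gene specificity*

    s_g^i = g_i / ((1/N) * Σ_{k=1..N} g_k),

i.e. each gene is divided by its mean over the N neighborhoods of its own
dataset. This removes per-gene scale — differences in quantification,
normalization depth, or absolute expression between datasets — so that the
Pearson correlation of specificity rows across species is a meaningful
similarity. The full N_A × N_B correlation matrix is reduced to
max-correlation maps (per neighborhood, the best partner in the other
species, ties to the smallest partner index), aggregated by the cell type
of each neighborhood's index cell, and to the union of argmax pairs in both
directions.

### Shared feature set

Features are selected per species as the top 2,000 genes by biological
variance (total variance of log-normalized expression minus a fitted
mean-variance trend), excluding mitochondrial genes (ID prefix `MT-` plus
any explicit list) and a user-supplied cell-cycle list, restricted to
one-to-one orthologs, and intersected through the ortholog mapping. The
trend is a least-squares quadratic in the per-gene mean, clipped at zero; a
local (loess-like) fit could be substituted behind the same contract, but
for *ranking* genes the quadratic is adequate and exactly deterministic.
Ties in biological variance break lexicographically by gene ID. Exclusion
lists are applied after taking the top set by default (`exclude_before_top`
flips the order); the two orders commute for the final intersection in all
but contrived cases.

### Normalization

Counts are normalized by mean-centred library-size factors
f_c = total_c / mean(total) and log-transformed as log2(1 + count/f_c).
Pooled deconvolution size factors are a common alternative; library-size
factors are a deliberate simplification here because the downstream
specificity scaling divides out per-gene scale anyway, making the
comparison insensitive to the choice. The log base is a configuration knob
(base 2 by default).

### Numerical choices

- PCA uses a full SVD; each component's sign is fixed by making its
  largest-magnitude loading positive, so embeddings are bit-reproducible.
- Zero-variance specificity rows produce NaN correlations, which are masked
  and never imputed; maxima are taken over defined entries only.
- Genes whose profile mean is zero in either species are dropped from the
  specificity step (the division is undefined) and recorded, never silently.
- Specificity is computed after subsetting to the shared features (a config
  switch to the pipeline could scale over the full gene universe instead;
  the subset-first order is the default and the one all results here use).
- The self-comparison identity (comparing a dataset with itself must return
  max correlation exactly 1.0 at itself) requires both "species" to draw
  identical neighborhoods on identical inputs, so the pipeline derives one
  sampling seed and shares it across the two per-species sampling stages.
- Argmax ties break to the smallest partner index; candidate refinement
  ties break to the smallest cell index.

## 3' annotation extension

Droplet scRNA-seq reads concentrate at transcript 3' ends; on sparsely
annotated genomes many reads fall just downstream of the annotated 3' end
and are discarded as intergenic. The module measures, for every intergenic
read, the distance to the nearest same-chromosome, same-strand gene 3' end
(downstream side only; the first base after the 3' end has distance 1;
reads with no upstream gene land in an "unassigned" bucket). Guided by that
histogram, gene 3' annotations are extended by a fixed length (default
600 bp — in the motivating data the majority of intergenic reads fell
within 600 bp of a 3' end). Extensions are all-or-nothing: a gene is left
bit-identical when its extended interval would overlap any other gene's
records. The overlap test is strand-agnostic by default (safer for
unstranded counting; a same-strand-only switch exists) and sees previously
accepted extensions, so extended outputs never contain overlapping
annotations of different genes. An optional truncate mode shrinks a blocked
extension to abut the blocker instead. Each accepted extension moves the
gene and transcript 3' coordinates and appends a synthetic terminal exon
and CDS tagged `source "extension"`. Minus-strand extensions clip at
coordinate 1; plus-strand extensions clip at the chromosome end only when
chromosome lengths are supplied (GTF itself carries none).

Ortholog rescue runs after extension: per missing transcript, only
alignment segments tied for the maximum score are kept; a transcript is
rejected when kept segments span multiple chromosomes (or strands — a
conservative reading of the proximity requirement; no distance cap is
applied beyond same-chromosome) or overlap any existing annotation,
including extensions and previously accepted rescues. Accepted transcripts
become new gene/transcript/exon/CDS records tagged `source "rescue"`.

The `reassignment_gain` metric is a desk-scale proxy for the improvement in
counted reads: the fraction of formerly intergenic reads (recomputed
against the pre-extension models) covered by the post-extension models,
with same-strand coverage.

## Pseudotime smoothing

For trajectory heatmaps, per-gene expression is smoothed along a supplied
cell ordering with a centered moving average (window 49 cells, odd), the
window truncating symmetrically at the series ends so the output keeps the
series length. Smoothed values are min-max scaled to [0, 1] per gene;
z-score scaling is the variant for signed scores such as chromatin
accessibility deviations. Genes constant after smoothing map to all-zeros
and are reported. Pseudotime computation itself is out of scope: orderings
are inputs.

## The synthetic generator

The generator emulates the statistical structure the comparison assumes:
two species share latent cell-type programs over one-to-one orthologous
genes. Per-gene base means are lognormal(-1, 1); each cell type up-/down-
regulates a random 10% gene subset by lognormal(0, 1) fold effects;
divergent cell types have a `divergence` fraction of their program genes'
effects independently re-drawn in species B. Counts are gamma-Poisson
(negative binomial, variance µ + 0.5µ²) with lognormal(0, 0.35) library
scaling of the NB means. 80% of genes are one-to-one orthologs; half the
remainder map one-to-many (two independent species-B copies), half are
absent from species B. Gene IDs carry species prefixes (`gA_`/`gB_`) so the
pipeline must use the ortholog table. The default conditions are six shared
cell types plus one divergent type (divergence 0.8), 300 cells per type per
species, and 2,000 genes.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, uneven cell-type abundances, or continuous differentiation
trajectories (types are discrete). Passing the recovery checks therefore
demonstrates correctness of the pipeline's statistics and its behaviour
under the assumed generative structure — not robustness to the technical
artifacts real atlases carry, which the out-of-scope preprocessing
(barcode-swapping correction, batch integration) addresses upstream.

The toy genome is a set of evenly spaced two-exon genes with alternating
strands; 3'-biased reads are placed either uniformly within exons or
1..L_truth bp downstream of a random gene's 3' end, strand-aware.

## Problem sizes and runtime

All shipped checks run at desk scale: simulations of ~2,100 cells × 2,000
genes per species fit in seconds per pipeline run, and the ground-truth
recovery checks repeat the default conditions over five simulation seeds.
Full-atlas numbers (tens of thousands of neighborhoods from hundreds of
thousands of cells) are a property of the deposited atlas data. Validating
against those deposited accessions (scRNA-seq `E-MTAB-11836`, scATAC-seq
`E-MTAB-11804`, imaging `S-BIAD604`) is an optional, full-scale exercise:
it requires downloading the atlases and is deliberately not part of the
shipped test suite, which must run self-contained. At that scale the kNN
stage should switch to approximate search (a documented flag path);
desk-scale runs always use exact brute-force search.

## Known limitations

- The index-cell refinement matches the published description of the
  refined sampling scheme (nearest-to-neighbor-mean); exact parity with any
  particular implementation's internals (e.g. extra graph densification) is
  not claimed, so neighborhood counts/sizes on real atlases are
  approximate, not exact, reproductions.
- The quadratic mean-variance trend is a ranking device, not a calibrated
  noise model.
- The ortholog rescue applies no proximity cap beyond the same-chromosome
  (and same-strand) rule.
- Whether exclusion lists should apply before or after the top-HVG cut, and
  whether the extension overlap test should be strand-aware, are genuinely
  open choices; both are config switches with the defaults argued above.
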