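# nhoodcomp

Cross-species comparison of single-cell transcriptomes at the granularity
of kNN-graph neighborhoods, plus 3' annotation extension for 3'-biased
droplet scRNA-seq on sparsely annotated genomes.

## The problem

Comparing developmental atlases of two species (say rabbit and mouse
gastrulation) through annotated cell types hides everything the annotations
smooth over: continuous trajectories, granular states, and genuinely
divergent programs. `nhoodcomp` instead compares *neighborhoods* — for each
species, index cells sampled on the kNN graph of a PCA embedding, each
aggregated with its symmetrized graph adjacency. Every neighborhood is
summarised by its mean log-normalized expression profile g_i over a shared
feature set (the intersection of both species' top highly variable genes,
restricted to one-to-one orthologs, minus mitochondrial and cell-cycle
genes), rescaled to **gene specificity**

    s_g^i = g_i / ((1/N) Σ_{k=1..N} g_k)

so that per-gene scale — quantification and depth differences between
datasets — divides out. Pearson correlation of specificity rows over the
shared features gives an N_A × N_B similarity matrix; per neighborhood, the
*maximum* correlation across the other species (and its argmax partner)
measures how conserved that transcriptional state is, and aggregating those
maxima by the index cells' cell types ranks types from conserved to
divergent.

A companion module addresses a practical obstacle to such comparisons:
droplet scRNA-seq reads pile up at transcript 3' ends, so on sparsely
annotated genomes many reads land just downstream of annotated genes and go
uncounted. It histograms intergenic-read distances to the nearest gene 3'
end, extends gene annotations by a fixed length (default 600 bp) wherever
no other annotation blocks the extension, and rescues missing genes from
precomputed cross-species alignment intervals.

A synthetic two-species generator (shared latent cell-type programs over
one-to-one orthologs, configurable divergent types, negative-binomial
counts, lognormal library sizes, toy genomes with 3'-biased reads) makes
every stage testable against known ground truth without downloading any
atlas.

## Worked example

```python
from nhoodcomp import (SimulationConfig, simulate_species_pair,
                       NeighborhoodComparison, NeighborhoodConfig,
                       FeatureSelectionConfig)

cfg = SimulationConfig(n_cells_per_type=150, n_genes=1000, seed=3)
ds_a, ds_b, orthologs, truth = simulate_species_pair(cfg)
model = NeighborhoodComparison(
    ds_a, ds_b, orthologs,
    NeighborhoodConfig(k=20, n_pcs=30, n_hvgs=800, sampling_proportion=0.05, seed=0),
    FeatureSelectionConfig(n_top=800))
results = model.fit()
print(results.summary())
```

```
Cross-species neighborhood comparison
================================================
species A (A): 38 neighborhoods, mean size 69.8
species B (B): 33 neighborhoods, mean size 69.3
shared one-to-one features used: 574 (0 dropped for zero mean)
max correlation A->B: mean 0.510, median 0.498
max correlation B->A: mean 0.533, median 0.526

cell types ranked by mean max correlation (A->B):
  T6                   n=3     mean=0.713
  T1                   n=5     mean=0.621
  T2                   n=4     mean=0.564
  T3                   n=7     mean=0.536
  T4                   n=7     mean=0.475
  T5                   n=7     mean=0.434
  T7                   n=5     mean=0.349
```

The simulation's one divergent cell type (T7, 80% of its program genes
independently re-drawn in species B) lands at the bottom of the ranking:
its neighborhoods find no well-matching partner state in the other species,
exactly the signature the method is designed to expose. The six shared
types score higher, and their neighborhoods' argmax partners carry the
matching ground-truth label. `results` also exposes the full correlation
matrix, per-direction max-correlation tables, the bidirectional argmax pair
list, and the per-cell-type aggregation as DataFrames.

The same pipeline runs from the shell:

```bash
nhoodcomp simulate --out sim/ --cells-per-type 150 --genes 1000 --seed 3
nhoodcomp run-all --config run.yaml        # or: --seed 3 --out run/
nhoodcomp extend-gtf --gtf sim/models.gtf --out extended.gtf \
    --length 600 --reads sim/reads.tsv --hist hist.tsv
```

`run-all` writes every intermediate (features, correlation matrix, max
maps, neighborhood sets, summaries) as TSV/JSON plus a `manifest.json`
recording seed, parameters and per-file SHA-256 checksums; runs with the
same seed are checksum-identical.

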