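"""Synthetic two-species scRNA-seq generator with known ground truth.

Two species share latent cell-type expression programs over one-to-one
orthologous genes; a configurable subset of cell types is divergent, meaning
a fraction of its program genes is independently re-drawn in species B.
Counts are gamma-Poisson (negative binomial) with lognormal per-gene base
means and lognormal library sizes applied as per-cell scaling of the NB
means.  The generator also produces toy gene models and 3'-biased read
positions for the annotation-extension stage.

Gene IDs carry species-specific prefixes (``gA_``/``gB_``) with an explicit
ortholog mapping table, so the comparison pipeline must use the table rather
than name identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, write_counts
from .gtf import GeneModelSet, ReadLocus, write_gtf, write_read_loci
from .orthologs import OrthologTable, write_ortholog_table

PROGRAM_FRACTION = 0.10  # fraction of genes in each cell type's program


@dataclass
class SimulationConfig:
    """Conditions for the paired two-species simulation.

    Defaults describe six shared cell types plus one strongly divergent type
    (80% of its program genes re-drawn in species B), 300 cells per type per
    species, 2,000 genes of which 80% have one-to-one orthologs.
    """

    n_cell_types: int = 7
    n_divergent_types: int = 1
    n_cells_per_type: int = 300
    n_genes: int = 2000
    frac_one2one: float = 0.8
    program_effect_sd: float = 1.0  # lognormal sigma of per-type fold effects
    divergence: float = 0.8  # fraction of program genes re-drawn for divergent types
    nb_dispersion: float = 0.5  # var = mu + disp * mu^2
    libsize_mu: float = 0.0  # lognormal location of library scaling
    libsize_sd: float = 0.35
    base_mean_mu: float = -1.0  # lognormal location of per-gene base means
    base_mean_sd: float = 1.0
    seed: int = 0
    shared_types: tuple | None = None  # default: first n_cell_types - n_divergent_types labels
    divergent_types: tuple | None = None  # default: remaining labels

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_cells_per_type <= 0 or self.n_cell_types <= 0:
            raise ValueError("n_genes, n_cells_per_type and n_cell_types must be positive")
        if not 0 <= self.n_divergent_types <= self.n_cell_types:
            raise ValueError("n_divergent_types out of range")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if not 0.0 <= self.frac_one2one <= 1.0:
            raise ValueError("frac_one2one must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        labels = tuple(f"T{i + 1}" for i in range(self.n_cell_types))
        n_shared = self.n_cell_types - self.n_divergent_types
        if self.shared_types is None:
            self.shared_types = labels[:n_shared]
        else:
            self.shared_types = tuple(self.shared_types)
        if self.divergent_types is None:
            self.divergent_types = tuple(t for t in labels if t not in self.shared_types)
        else:
            self.divergent_types = tuple(self.divergent_types)
        if set(self.shared_types) & set(self.divergent_types):
            raise ValueError("shared_types and divergent_types must be disjoint")

    @property
    def cell_types(self) -> tuple:
        return self.shared_types + self.divergent_types


@dataclass
class GroundTruth:
    """What the generator knows: labels, ortholog classes, latent programs."""

    cell_types_a: list
    cell_types_b: list
    ortholog_class: dict  # species-A gene ID -> one2one | one2many | absent
    divergent_flag: dict  # cell type -> bool
    program_a: pd.DataFrame  # genes_a x types, latent mean expression
    program_b: pd.DataFrame  # genes_b x types


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def simulate_species_pair(config: SimulationConfig):
    """Generate matched species A/B datasets, ortholog table and ground truth.

    Returns ``(dataset_a, dataset_b, orthologs, truth)``.  For shared cell
    types the per-type latent programs of A and B are identical over
    one-to-one ortholog genes; for divergent types a ``config.divergence``
    fraction of program genes is independently re-drawn in species B.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    types = list(config.cell_types)

    genes_a = [f"gA_{i + 1:05d}" for i in range(G)]
    base_mean = rng.lognormal(config.base_mean_mu, config.base_mean_sd, size=G)

    # per-type multiplicative programs on a random 10% gene subset
    n_prog = max(1, int(round(PROGRAM_FRACTION * G)))
    effects_a = np.ones((G, len(types)))
    program_genes: dict[str, np.ndarray] = {}
    for j, t in enumerate(types):
        idx = rng.choice(G, size=n_prog, replace=False)
        program_genes[t] = np.sort(idx)
        effects_a[idx, j] = rng.lognormal(0.0, config.program_effect_sd, size=n_prog)

    # ortholog classes for species-A genes
    u = rng.random(G)
    classes = np.where(u < config.frac_one2one, "one2one", np.where(u < (1 + config.frac_one2one) / 2, "one2many", "absent"))

    # species-B gene universe: one2one partners keep A's parameters;
    # one2many copies get independent parameters
    genes_b, base_mean_b_rows, effects_b_rows, orth_rows = [], [], [], []
    for i, gene_a in enumerate(genes_a):
        if classes[i] == "one2one":
            gene_b = f"gB_{i + 1:05d}"
            genes_b.append(gene_b)
            base_mean_b_rows.append(base_mean[i])
            effects_b_rows.append(effects_a[i].copy())
            orth_rows.append((gene_a, gene_b, "one2one"))
        elif classes[i] == "one2many":
            for copy in (1, 2):
                gene_b = f"gB_{i + 1:05d}_{copy}"
                genes_b.append(gene_b)
                base_mean_b_rows.append(rng.lognormal(config.base_mean_mu, config.base_mean_sd))
                eff = np.ones(len(types))
                for j in range(len(types)):
                    if rng.random() < PROGRAM_FRACTION:
                        eff[j] = rng.lognormal(0.0, config.program_effect_sd)
                effects_b_rows.append(eff)
                orth_rows.append((gene_a, gene_b, "one2many"))
    base_mean_b = np.array(base_mean_b_rows)
    effects_b = np.array(effects_b_rows)

    # divergence: re-draw a fraction of program-gene effects in species B
    a_index = {g: i for i, g in enumerate(genes_a)}
    b_partner_of_a = {}
    for gene_a, gene_b, ht in orth_rows:
        if ht == "one2one":
            b_partner_of_a[gene_a] = gene_b
    b_index = {g: i for i, g in enumerate(genes_b)}
    for j, t in enumerate(types):
        if t not in config.divergent_types:
            continue
        prog = program_genes[t]
        n_redraw = int(round(config.divergence * len(prog)))
        redraw = rng.choice(prog, size=n_redraw, replace=False)
        for gi in redraw:
            gene_a = genes_a[gi]
            if gene_a in b_partner_of_a:
                bi = b_index[b_partner_of_a[gene_a]]
                effects_b[bi, j] = rng.lognormal(0.0, config.program_effect_sd)

    program_a = pd.DataFrame(base_mean[:, None] * effects_a, index=genes_a, columns=types)
    program_b = pd.DataFrame(base_mean_b[:, None] * effects_b, index=genes_b, columns=types)

    # draw counts: per cell, NB with mean = libfactor * base_mean * effect
    def _draw(genes, base, effects, species):
        n_cells = config.n_cells_per_type * len(types)
        counts = np.empty((n_cells, len(genes)), dtype=np.int64)
        labels, cell_ids = [], []
        row = 0
        for j, t in enumerate(types):
            mu_type = base * effects[:, j]
            lib = rng.lognormal(config.libsize_mu, config.libsize_sd, size=config.n_cells_per_type)
            mean = lib[:, None] * mu_type[None, :]
            counts[row : row + config.n_cells_per_type] = _nb_counts(rng, mean, config.nb_dispersion)
            labels.extend([t] * config.n_cells_per_type)
            cell_ids.extend(f"{species}_{t}_{c + 1:04d}" for c in range(config.n_cells_per_type))
            row += config.n_cells_per_type
        meta = pd.DataFrame({"species": species, "stage": "S1", "cell_type": labels}, index=cell_ids)
        return ExpressionDataset(counts, genes, cell_ids, meta), labels

    ds_a, labels_a = _draw(genes_a, base_mean, effects_a, "A")
    ds_b, labels_b = _draw(genes_b, base_mean_b, effects_b, "B")

    orthologs = OrthologTable(pd.DataFrame(orth_rows, columns=["gene_a", "gene_b", "homology_type"]))
    truth = GroundTruth(
        cell_types_a=labels_a,
        cell_types_b=labels_b,
        ortholog_class={g: str(classes[a_index[g]]) for g in genes_a},
        divergent_flag={t: (t in config.divergent_types) for t in types},
        program_a=program_a,
        program_b=program_b,
    )
    return ds_a, ds_b, orthologs, truth


# -- toy genome ----------------------------------------------------------


def simulate_gene_models(
    n_genes: int = 20,
    gene_length: int = 1000,
    spacing: int = 5000,
    n_chroms: int = 2,
    seed: int = 0,
) -> GeneModelSet:
    """Toy gene models: evenly spaced two-exon genes with alternating strands.

    ``spacing`` is the gap between consecutive gene spans; choose it larger
    than the intended 3' extension length to leave room downstream of every
    gene.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    per_chrom = int(np.ceil(n_genes / n_chroms))
    g = 0
    for c in range(n_chroms):
        pos = spacing + 1
        for _ in range(per_chrom):
            if g >= n_genes:
                break
            g += 1
            gid = f"gene{g:03d}"
            tid = f"tx{g:03d}"
            chrom = f"chr{c + 1}"
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = pos, pos + gene_length - 1
            exon1 = (start, start + gene_length // 3)
            exon2 = (end - gene_length // 3, end)
            rows.append(("gene", chrom, start, end, strand, gid, "", ""))
            rows.append(("transcript", chrom, start, end, strand, gid, tid, ""))
            for es, ee in (exon1, exon2):
                rows.append(("exon", chrom, es, ee, strand, gid, tid, ""))
                rows.append(("CDS", chrom, es, ee, strand, gid, tid, ""))
            pos = end + spacing + 1
    return GeneModelSet(
        pd.DataFrame(rows, columns=["feature_type", "chrom", "start", "end", "strand", "gene_id", "transcript_id", "source_tag"])
    )


def simulate_read_positions(
    models: GeneModelSet,
    n_reads: int,
    extension_truth: int,
    seed: int = 0,
    intergenic_fraction: float = 0.5,
) -> list[ReadLocus]:
    """Place 3'-biased reads on a toy genome.

    A ``1 - intergenic_fraction`` share of reads falls uniformly within
    annotated exons (class ``exonic``); the remainder falls 1..``extension_truth``
    bp downstream of a random gene's annotated 3' end, strand-aware, mimicking
    reads from unannotated 3' UTR (class ``intergenic``).
    """
    if extension_truth <= 0:
        raise ValueError("extension_truth must be positive")
    if not 0.0 <= intergenic_fraction <= 1.0:
        raise ValueError("intergenic_fraction must lie in [0, 1]")
    if len(models.gene_records()) == 0:
        raise ValueError("empty gene model set")
    rng = np.random.default_rng(seed)
    genes = models.gene_records()
    exons = models.exon_records()
    exons_by_gene = {gid: sub for gid, sub in exons.groupby("gene_id")}
    ends = models.three_prime_ends().set_index("gene_id")
    reads: list[ReadLocus] = []
    gene_ids = genes["gene_id"].tolist()
    for _ in range(n_reads):
        gid = gene_ids[rng.integers(len(gene_ids))]
        info = ends.loc[gid]
        if rng.random() < intergenic_fraction:
            if info["strand"] == "+":
                d = int(rng.integers(1, extension_truth + 1))
                pos = int(info["three_prime"]) + d
            else:
                hi = min(extension_truth, int(info["three_prime"]) - 1)
                if hi < 1:  # gene abuts the chromosome start; fall back to exonic
                    sub = exons_by_gene[gid]
                    row = sub.iloc[int(rng.integers(len(sub)))]
                    pos = int(rng.integers(row["start"], row["end"] + 1))
                    reads.append(ReadLocus(str(info["chrom"]), pos, str(info["strand"]), "exonic"))
                    continue
                d = int(rng.integers(1, hi + 1))
                pos = int(info["three_prime"]) - d
            reads.append(ReadLocus(str(info["chrom"]), pos, str(info["strand"]), "intergenic"))
        else:
            sub = exons_by_gene[gid]
            row = sub.iloc[int(rng.integers(len(sub)))]
            pos = int(rng.integers(row["start"], row["end"] + 1))
            reads.append(ReadLocus(str(info["chrom"]), pos, str(info["strand"]), "exonic"))
    return reads


def write_species_pair(outdir, ds_a, ds_b, orthologs, truth=None) -> dict:
    """Dump a simulated pair as mtx + TSV sidecars; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, ds in (("a", ds_a), ("b", ds_b)):
        paths[tag] = {
            "matrix": outdir / f"species_{tag}.mtx",
            "genes": outdir / f"species_{tag}_genes.tsv",
            "cells": outdir / f"species_{tag}_cells.tsv",
            "meta": outdir / f"species_{tag}_meta.tsv",
        }
        write_counts(ds, paths[tag]["matrix"], paths[tag]["genes"], paths[tag]["cells"], paths[tag]["meta"])
    paths["orthologs"] = outdir / "orthologs.tsv"
    write_ortholog_table(orthologs, paths["orthologs"])
    return paths
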