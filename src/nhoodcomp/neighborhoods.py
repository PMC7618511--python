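"""Per-species PCA embedding, kNN graph, and refined neighborhood sampling.

A neighborhood is the set of cells adjacent (in the symmetrized kNN graph)
to a chosen index cell, plus the index cell itself.  Index cells are drawn
by uniform sampling followed by a refinement step that moves each candidate
to the most representative cell of its graph vicinity, preventing
oversampling and producing larger neighborhoods than the raw k would give.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .datasets import ExpressionDataset
from .features import model_gene_variance


@dataclass
class NeighborhoodConfig:
    """k (default 30), embedding dimensionality (default 50 PCs), sampling
    proportion of index-cell candidates (default 0.05), and the RNG seed."""

    k: int = 30
    n_pcs: int = 50
    n_hvgs: int = 2000
    sampling_proportion: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.sampling_proportion <= 1:
            raise ValueError("sampling_proportion must lie in (0, 1]")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")


@dataclass
class Embedding:
    """Cells x d real coordinate matrix aligned with a dataset's cell IDs."""

    matrix: np.ndarray
    cell_ids: list

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("embedding must be 2-D with >= 1 column")
        if self.matrix.shape[0] != len(self.cell_ids):
            raise ValueError("embedding rows must match cell IDs")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]


class KnnGraph:
    """Directed k-nearest lists plus the symmetrized (union) adjacency."""

    def __init__(self, neighbors: np.ndarray, cell_ids: list):
        neighbors = np.asarray(neighbors, dtype=np.int64)
        n, k = neighbors.shape
        if n != len(cell_ids):
            raise ValueError("neighbor rows must match cell IDs")
        if np.any(neighbors == np.arange(n)[:, None]):
            raise ValueError("self-edges are not allowed")
        self.neighbors = neighbors
        self.cell_ids = list(cell_ids)
        rows = np.repeat(np.arange(n), k)
        cols = neighbors.ravel()
        adj = sp.coo_matrix((np.ones(n * k, dtype=bool), (rows, cols)), shape=(n, n)).tocsr()
        self.adjacency = (adj + adj.T).astype(bool).tocsr()  # union of directed edges

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    def symmetrized_neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]]


@dataclass
class NeighborhoodSet:
    """Index cells with their member sets over one species' kNN graph."""

    index_cells: list  # cell IDs of the (deduplicated) refined index cells
    members: list  # per-neighborhood sets of cell IDs
    index_positions: np.ndarray  # integer positions of index cells

    def __post_init__(self):
        if len(self.index_cells) != len(self.members):
            raise ValueError("index_cells and members length mismatch")
        if len(set(self.index_cells)) != len(self.index_cells):
            raise ValueError("index cells must be unique")
        for idx, mem in zip(self.index_cells, self.members):
            if idx not in mem:
                raise ValueError(f"neighborhood of {idx} does not contain its index cell")

    @property
    def N(self) -> int:
        return len(self.index_cells)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=np.int64)


def compute_embedding(dataset: ExpressionDataset, n_hvgs: int = 2000, n_pcs: int = 50) -> Embedding:
    """PCA of centered log-normalized expression of the top HVGs.

    Components are ordered by decreasing explained variance and the sign of
    each is fixed by making its largest-magnitude gene loading positive, so
    the embedding is deterministic for a fixed input.
    """
    layer = dataset.require_log_layer()
    if n_pcs > min(dataset.n_cells, dataset.n_genes):
        raise ValueError("n_pcs exceeds min(n_cells, n_genes)")
    vm = model_gene_variance(dataset)
    top = vm.top_genes(min(n_hvgs, dataset.n_genes))
    col = {g: i for i, g in enumerate(dataset.gene_ids)}
    cols = [col[g] for g in top]
    X = np.asarray(layer[:, cols].todense(), dtype=float)
    X -= X.mean(axis=0)
    # full SVD keeps the decomposition deterministic
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    for j in range(n_pcs):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    return Embedding(scores, dataset.cell_ids)


def build_knn_graph(embedding: Embedding, k: int = 30) -> KnnGraph:
    """Euclidean kNN graph, self excluded, exact (brute-force) search."""
    n = embedding.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    algorithm = "brute" if n <= 50_000 else "auto"
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm=algorithm, metric="euclidean")
    nn.fit(embedding.matrix)
    idx = nn.kneighbors(embedding.matrix, return_distance=False)
    # drop self wherever it appears in the first k+1 hits
    neighbors = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        neighbors[i] = row
    return KnnGraph(neighbors, embedding.cell_ids)


def sample_neighborhoods(graph: KnnGraph, embedding: Embedding, config: NeighborhoodConfig) -> NeighborhoodSet:
    """Sample index cells, refine them, and aggregate their graph vicinities.

    1. draw ``ceil(p * n)`` candidate cells as a prefix of a seeded random
       permutation (so increasing p only adds candidates);
    2. refine each candidate to the cell — among the candidate and its
       symmetrized graph neighbors — nearest to the mean embedding position
       of those neighbors;
    3. deduplicate refined indices;
    4. each neighborhood is its refined index cell plus that cell's full
       symmetrized adjacency set.
    """
    n = graph.n_cells
    if n == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(config.seed)
    n_cand = math.ceil(config.sampling_proportion * n)
    candidates = rng.permutation(n)[:n_cand]
    refined = []
    for c in candidates:
        nbrs = graph.symmetrized_neighbors(int(c))
        if nbrs.size == 0:
            refined.append(int(c))
            continue
        mean_pos = embedding.matrix[nbrs].mean(axis=0)
        pool = np.concatenate([nbrs, [c]])
        pool = np.unique(pool)  # sorted: ties resolve to the smallest index
        dists = np.linalg.norm(embedding.matrix[pool] - mean_pos, axis=1)
        refined.append(int(pool[np.argmin(dists)]))
    index_positions = np.unique(np.array(refined, dtype=np.int64))
    members = []
    for i in index_positions:
        mem = set(graph.symmetrized_neighbors(int(i)).tolist()) | {int(i)}
        members.append({graph.cell_ids[j] for j in mem})
    index_cells = [graph.cell_ids[int(i)] for i in index_positions]
    return NeighborhoodSet(index_cells, members, index_positions)


def neighborhood_stats(nhoods: NeighborhoodSet):
    """(N, mean size, size distribution) of a neighborhood set."""
    if nhoods.N == 0:
        raise ValueError("empty neighborhood set")
    sizes = nhoods.sizes
    return nhoods.N, float(sizes.mean()), sizes
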