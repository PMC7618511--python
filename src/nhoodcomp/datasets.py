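"""Expression dataset container, matrix-market I/O, and library-size normalization.

The in-memory container is :class:`anndata.AnnData` (cells x genes, sparse
integer counts); :class:`ExpressionDataset` is a thin validated wrapper that
fixes the metadata contract (``species``, ``stage``, ``cell_type`` per cell)
and the layer name used for log-normalized expression.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

LOG_LAYER = "lognorm"
META_COLUMNS = ("species", "stage", "cell_type")


class ExpressionDataset:
    """Cells x genes counts with gene IDs and per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells x genes (dense or sparse).
    gene_ids, cell_ids
        Unique string identifiers matching the matrix dimensions.
    cell_meta
        Optional per-cell DataFrame; ``species``, ``stage`` and ``cell_type``
        columns are created (empty) when missing.
    """

    def __init__(self, counts, gene_ids, cell_ids, cell_meta: pd.DataFrame | None = None):
        counts = sp.csr_matrix(counts)
        gene_ids = [str(g) for g in gene_ids]
        cell_ids = [str(c) for c in cell_ids]
        if counts.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(cell_ids)} cells x {len(gene_ids)} genes"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(cell_ids)) != len(cell_ids):
            raise ValueError("duplicate cell IDs")
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("negative count entries")
        if cell_meta is None:
            cell_meta = pd.DataFrame(index=cell_ids)
        else:
            cell_meta = cell_meta.copy()
            cell_meta.index = pd.Index(cell_ids)
        for col in META_COLUMNS:
            if col not in cell_meta.columns:
                cell_meta[col] = ""
        self.adata = ad.AnnData(
            X=counts,
            obs=cell_meta,
            var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
        )

    # -- accessors -------------------------------------------------------

    @property
    def counts(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.adata.X)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.adata.var_names)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.adata.obs_names)

    @property
    def cell_meta(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    @property
    def log_layer(self) -> sp.csr_matrix | None:
        if LOG_LAYER in self.adata.layers:
            return sp.csr_matrix(self.adata.layers[LOG_LAYER])
        return None

    def require_log_layer(self) -> sp.csr_matrix:
        layer = self.log_layer
        if layer is None:
            raise ValueError("log-normalized layer missing; run log_normalize first")
        return layer

    def set_embedding(self, name: str, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[0] != self.n_cells:
            raise ValueError("embedding rows must match cell count")
        self.adata.obsm[name] = matrix

    def get_embedding(self, name: str) -> np.ndarray | None:
        return self.adata.obsm.get(name)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionDataset({self.n_cells} cells x {self.n_genes} genes)"


def log_normalize(dataset: ExpressionDataset, base: float = 2.0) -> ExpressionDataset:
    """Attach a log-normalized layer using mean-centred library-size factors.

    The size factor of cell *c* is ``f_c = total_c / mean(total)``, so factors
    average to 1 across cells, and the layer entry is
    ``log_base(1 + count / f_c)``.  Cells with zero total counts are rejected
    because their size factor is undefined.

    Returns the same dataset (layer added in place) for chaining.
    """
    counts = dataset.counts.astype(float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = [dataset.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"cells with zero total counts: {bad}")
    factors = totals / totals.mean()
    scaled = sp.diags(1.0 / factors) @ counts
    scaled.data = np.log1p(scaled.data) / np.log(base)
    dataset.adata.layers[LOG_LAYER] = sp.csr_matrix(scaled)
    return dataset


def size_factors(dataset: ExpressionDataset) -> np.ndarray:
    """Library-size factors ``total_c / mean(total)`` (mean 1 by construction)."""
    totals = np.asarray(dataset.counts.sum(axis=1)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts")
    return totals / totals.mean()


# -- matrix-market triplet I/O ------------------------------------------


def read_counts(matrix_path, genes_path, cells_path, meta_path=None) -> ExpressionDataset:
    """Read a cells x genes dataset from .mtx + gene/cell TSV sidecars.

    The gene and cell files are one-column (ID) or multi-column TSVs whose
    first column is the ID; an optional metadata TSV (indexed by cell ID)
    supplies ``species``/``stage``/``cell_type``.
    """
    matrix = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))

    def _ids(path):
        lines = Path(path).read_text().splitlines()
        return [line.split("\t")[0] for line in lines if line]

    genes = _ids(genes_path)
    cells = _ids(cells_path)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
        meta = meta.reindex(cells)
    return ExpressionDataset(matrix, genes, cells, meta)


def write_counts(dataset: ExpressionDataset, matrix_path, genes_path, cells_path, meta_path=None) -> None:
    """Write the triplet representation read back by :func:`read_counts`."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(dataset.counts), field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in dataset.gene_ids))
    Path(cells_path).write_text("".join(f"{c}\n" for c in dataset.cell_ids))
    if meta_path is not None:
        dataset.cell_meta.to_csv(meta_path, sep="\t", index_label="cell_id")
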