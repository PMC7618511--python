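"""Highly variable gene modelling and shared cross-species feature selection.

Genes are ranked by "biological" variance — total variance of log-normalized
expression minus a smooth mean-variance trend capturing the technical
component.  The shared feature set is the intersection of both species' top
HVGs, after excluding mitochondrial and cell-cycle genes, restricted to
one-to-one orthologs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .orthologs import OrthologTable


@dataclass
class VarianceModel:
    """Per-gene mean, total variance, fitted trend and biological variance."""

    table: pd.DataFrame  # index gene_id; columns mean, total_variance, trend, bio_variance

    def top_genes(self, n: int) -> list[str]:
        """Top-n genes by biological variance, ties broken lexicographically."""
        ranked = self.table.sort_values(
            ["bio_variance", "gene_id"], ascending=[False, True], key=None
        )
        return ranked.index[:n].tolist()


@dataclass
class FeatureSelectionConfig:
    n_top: int = 2000
    mito_prefix: str = "MT-"
    mito_genes: tuple = field(default_factory=tuple)
    cell_cycle_genes: tuple = field(default_factory=tuple)
    # if True, exclusion lists are applied before taking the top n_top
    exclude_before_top: bool = False

    def __post_init__(self):
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")


def model_gene_variance(dataset: ExpressionDataset) -> VarianceModel:
    """Fit the mean-variance trend of log-normalized expression.

    The technical trend is a least-squares second-degree polynomial of the
    per-gene variance against the per-gene mean, clipped at 0; biological
    variance is total minus trend.
    """
    layer = dataset.require_log_layer()
    if dataset.n_cells < 3:
        raise ValueError("variance modelling requires at least 3 cells")
    dense = np.asarray(layer.todense(), dtype=float)
    mean = dense.mean(axis=0)
    var = dense.var(axis=0, ddof=1)
    if np.unique(mean).size < 3:
        trend = np.full_like(var, max(var.mean(), 0.0))
    else:
        coeffs = np.polyfit(mean, var, deg=2)
        trend = np.clip(np.polyval(coeffs, mean), 0.0, None)
    table = pd.DataFrame(
        {
            "mean": mean,
            "total_variance": var,
            "trend": trend,
            "bio_variance": var - trend,
        },
        index=pd.Index(dataset.gene_ids),
    )
    table["gene_id"] = table.index
    return VarianceModel(table)


def _excluded(gene_ids, config: FeatureSelectionConfig) -> set:
    out = set()
    for g in gene_ids:
        if config.mito_prefix and g.upper().startswith(config.mito_prefix.upper()):
            out.add(g)
    out |= set(config.mito_genes) & set(gene_ids)
    out |= set(config.cell_cycle_genes) & set(gene_ids)
    return out


def select_shared_features(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    orthologs: OrthologTable,
    config: FeatureSelectionConfig | None = None,
) -> pd.DataFrame:
    """Build the ordered (gene_a, gene_b) shared feature list.

    Pipeline: top ``n_top`` HVGs per species independently; drop excluded
    (mitochondrial + cell-cycle) genes per species; restrict to one-to-one
    ortholog rows; keep a pair iff both sides survive in their species.
    Output sorted by ``gene_a``.  An empty result is a warning, not an error.
    """
    config = config or FeatureSelectionConfig()
    sets = {}
    for tag, ds in (("a", ds_a), ("b", ds_b)):
        vm = model_gene_variance(ds)
        excl = _excluded(ds.gene_ids, config)
        if config.exclude_before_top:
            keep = vm.table.index[~vm.table.index.isin(excl)]
            vm = VarianceModel(vm.table.loc[keep])
            sets[tag] = set(vm.top_genes(config.n_top))
        else:
            sets[tag] = set(vm.top_genes(config.n_top)) - excl
    one2one = orthologs.one2one()
    pairs = one2one[one2one["gene_a"].isin(sets["a"]) & one2one["gene_b"].isin(sets["b"])]
    pairs = pairs[["gene_a", "gene_b"]].sort_values("gene_a").reset_index(drop=True)
    if pairs.empty:
        warnings.warn("shared feature set is empty", stacklevel=2)
    return pairs
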