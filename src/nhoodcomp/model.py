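"""Model/results interface for the cross-species neighborhood comparison.

:class:`NeighborhoodComparison` is built from two expression datasets and an
ortholog table; ``fit()`` runs the full pipeline — normalization, per-species
embedding, kNN graph, refined neighborhood sampling, shared feature
selection, neighborhood profiles, gene specificity, the cross-species
correlation matrix — and returns a :class:`NeighborhoodComparisonResults`
carrying the correlation matrix, per-direction max-correlation maps,
cell-type aggregations and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .compare import (
    CrossSpeciesCorrelation,
    MaxCorrelationMap,
    NeighborhoodProfileMatrix,
    SpecificityMatrix,
    aggregate_by_cell_type,
    bidirectional_mapping,
    cross_correlation,
    max_correlation,
    neighborhood_means,
)
from .datasets import ExpressionDataset, LOG_LAYER, log_normalize
from .features import FeatureSelectionConfig, select_shared_features
from .neighborhoods import (
    Embedding,
    NeighborhoodConfig,
    NeighborhoodSet,
    build_knn_graph,
    compute_embedding,
    sample_neighborhoods,
)
from .orthologs import OrthologTable


class PipelineStageError(RuntimeError):
    """An error raised by one named stage of the comparison pipeline."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class NeighborhoodComparisonResults:
    """Fitted quantities of a cross-species neighborhood comparison."""

    correlation: CrossSpeciesCorrelation
    max_a_to_b: MaxCorrelationMap
    max_b_to_a: MaxCorrelationMap
    celltype_summary_a: pd.DataFrame
    celltype_summary_b: pd.DataFrame
    pairs: pd.DataFrame  # bidirectional argmax mapping
    features: pd.DataFrame  # (gene_a, gene_b) shared feature pairs used
    dropped_features: pd.DataFrame  # pairs dropped for zero mean in either species
    nhoods_a: NeighborhoodSet
    nhoods_b: NeighborhoodSet
    profiles_a: NeighborhoodProfileMatrix
    profiles_b: NeighborhoodProfileMatrix
    specificity_a: SpecificityMatrix
    specificity_b: SpecificityMatrix
    embedding_a: Embedding
    embedding_b: Embedding
    species_a: str = "A"
    species_b: str = "B"

    def summary(self) -> str:
        """Human-readable fit summary."""
        sizes_a, sizes_b = self.nhoods_a.sizes, self.nhoods_b.sizes
        vals_a = self.max_a_to_b.table.loc[self.max_a_to_b.table["defined"], "max_corr"]
        vals_b = self.max_b_to_a.table.loc[self.max_b_to_a.table["defined"], "max_corr"]
        lines = [
            "Cross-species neighborhood comparison",
            "=" * 48,
            f"species A ({self.species_a}): {self.nhoods_a.N} neighborhoods, "
            f"mean size {sizes_a.mean():.1f}",
            f"species B ({self.species_b}): {self.nhoods_b.N} neighborhoods, "
            f"mean size {sizes_b.mean():.1f}",
            f"shared one-to-one features used: {len(self.features)} "
            f"({len(self.dropped_features)} dropped for zero mean)",
            f"max correlation A->B: mean {vals_a.mean():.3f}, median {vals_a.median():.3f}",
            f"max correlation B->A: mean {vals_b.mean():.3f}, median {vals_b.median():.3f}",
            "",
            "cell types ranked by mean max correlation (A->B):",
        ]
        for rec in self.celltype_summary_a.itertuples(index=False):
            lines.append(f"  {rec.cell_type:<20s} n={rec.n:<5d} mean={rec.mean_max_corr:.3f}")
        return "\n".join(lines)


class NeighborhoodComparison:
    """Compare two species' transcriptional landscapes neighborhood-by-neighborhood.

    Parameters
    ----------
    dataset_a, dataset_b
        Counts + metadata per species; log-normalized in place when the
        layer is missing.
    orthologs
        Cross-species gene homology table; only one-to-one rows are used.
    nhood_config, feature_config
        Neighborhood-graph and feature-selection parameters (defaults: k=30,
        50 PCs, sampling proportion 0.05, top 2000 HVGs).
    embedding_key
        Optional name of a precomputed embedding stored on the datasets
        (``dataset.set_embedding``); skips the PCA stage when present.
    """

    def __init__(
        self,
        dataset_a: ExpressionDataset,
        dataset_b: ExpressionDataset,
        orthologs: OrthologTable,
        nhood_config: NeighborhoodConfig | None = None,
        feature_config: FeatureSelectionConfig | None = None,
        embedding_key: str | None = None,
        species_a: str = "A",
        species_b: str = "B",
    ):
        self.dataset_a = dataset_a
        self.dataset_b = dataset_b
        self.orthologs = orthologs
        self.nhood_config = nhood_config or NeighborhoodConfig()
        self.feature_config = feature_config or FeatureSelectionConfig()
        self.embedding_key = embedding_key
        self.species_a = species_a
        self.species_b = species_b

    def _stage(self, stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    def fit(self) -> NeighborhoodComparisonResults:
        cfg = self.nhood_config
        for ds in (self.dataset_a, self.dataset_b):
            if LOG_LAYER not in ds.adata.layers:
                self._stage("normalize", log_normalize, ds)

        embeddings = []
        for ds in (self.dataset_a, self.dataset_b):
            pre = ds.get_embedding(self.embedding_key) if self.embedding_key else None
            if pre is not None:
                embeddings.append(Embedding(pre, ds.cell_ids))
            else:
                embeddings.append(
                    self._stage("embed", compute_embedding, ds, cfg.n_hvgs, cfg.n_pcs)
                )
        emb_a, emb_b = embeddings

        graph_a = self._stage("graph", build_knn_graph, emb_a, cfg.k)
        graph_b = self._stage("graph", build_knn_graph, emb_b, cfg.k)

        # both species draw neighborhoods from the same seed so that
        # identical inputs yield identical neighborhood sets
        nh_a = self._stage("neighborhoods", sample_neighborhoods, graph_a, emb_a, cfg)
        nh_b = self._stage("neighborhoods", sample_neighborhoods, graph_b, emb_b, cfg)

        features = self._stage(
            "features",
            select_shared_features,
            self.dataset_a,
            self.dataset_b,
            self.orthologs,
            self.feature_config,
        )
        if features.empty:
            raise PipelineStageError("features", ValueError("no shared features selected"))

        prof_a = self._stage(
            "profiles", neighborhood_means, self.dataset_a, nh_a, features["gene_a"].tolist()
        )
        prof_b = self._stage(
            "profiles", neighborhood_means, self.dataset_b, nh_b, features["gene_b"].tolist()
        )

        # drop feature pairs with zero mean in either species, then scale
        mean_a = prof_a.values.mean(axis=0)
        mean_b = prof_b.values.mean(axis=0)
        keep = (mean_a > 0) & (mean_b > 0)
        dropped = features[~keep].reset_index(drop=True)
        kept = features[keep].reset_index(drop=True)
        spec_a = SpecificityMatrix(
            prof_a.values[:, keep] / mean_a[keep], prof_a.index_cells, kept["gene_a"].tolist()
        )
        spec_b = SpecificityMatrix(
            prof_b.values[:, keep] / mean_b[keep], prof_b.index_cells, kept["gene_b"].tolist()
        )

        # gene lists differ by species prefix but share the pairing order
        corr = self._stage(
            "correlation",
            cross_correlation,
            spec_a,
            SpecificityMatrix(spec_b.values, spec_b.index_cells, spec_a.gene_ids),
        )
        corr = CrossSpeciesCorrelation(corr.values, spec_a.index_cells, spec_b.index_cells)

        max_ab = self._stage("max_correlation", max_correlation, corr, "a_to_b")
        max_ba = self._stage("max_correlation", max_correlation, corr, "b_to_a")
        types_a = dict(zip(self.dataset_a.cell_ids, self.dataset_a.cell_meta["cell_type"]))
        types_b = dict(zip(self.dataset_b.cell_ids, self.dataset_b.cell_meta["cell_type"]))
        agg_a = self._stage("aggregate", aggregate_by_cell_type, max_ab, types_a)
        agg_b = self._stage("aggregate", aggregate_by_cell_type, max_ba, types_b)
        pairs = self._stage("pairs", bidirectional_mapping, corr)

        return NeighborhoodComparisonResults(
            correlation=corr,
            max_a_to_b=max_ab,
            max_b_to_a=max_ba,
            celltype_summary_a=agg_a,
            celltype_summary_b=agg_b,
            pairs=pairs,
            features=kept,
            dropped_features=dropped,
            nhoods_a=nh_a,
            nhoods_b=nh_b,
            profiles_a=prof_a,
            profiles_b=prof_b,
            specificity_a=spec_a,
            specificity_b=spec_b,
            embedding_a=emb_a,
            embedding_b=emb_b,
            species_a=self.species_a,
            species_b=self.species_b,
        )
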