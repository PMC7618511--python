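"""Neighborhood profiles, gene specificity, cross-species correlation maps,
cell-type aggregation, and ordered-expression smoothing.

The central statistic is gene specificity: the within-neighborhood mean
log-normalized expression of gene *g* in neighborhood *i*, divided by its
mean over all *N* neighborhoods,

    s_g^i = g_i / ((1/N) * sum_k g_k).

Dividing by the per-gene mean removes differences in quantification and
absolute scale between datasets, making profiles comparable across species;
Pearson correlation of specificity rows over the shared one-to-one ortholog
features then measures neighborhood similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .neighborhoods import NeighborhoodSet


@dataclass
class NeighborhoodProfileMatrix:
    """N x G within-neighborhood mean log-normalized expression."""

    values: np.ndarray
    index_cells: list  # per-row neighborhood index-cell IDs
    gene_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.index_cells), len(self.gene_ids)):
            raise ValueError("profile matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile matrix contains non-finite entries")
        if self.values.size and self.values.min() < 0:
            raise ValueError("log-normalized means must be non-negative")


@dataclass
class SpecificityMatrix:
    """N x G gene-specificity values; genes with zero mean are dropped."""

    values: np.ndarray
    index_cells: list
    gene_ids: list
    dropped_genes: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.index_cells), len(self.gene_ids)):
            raise ValueError("specificity matrix shape mismatch")


@dataclass
class CrossSpeciesCorrelation:
    """N_A x N_B Pearson correlations over shared genes; NaNs masked."""

    values: np.ndarray
    index_cells_a: list
    index_cells_b: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.index_cells_a), len(self.index_cells_b)):
            raise ValueError("correlation matrix shape mismatch")
        defined = self.values[~np.isnan(self.values)]
        if defined.size and (defined.min() < -1 - 1e-9 or defined.max() > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")

    @property
    def nan_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class MaxCorrelationMap:
    """Per-neighborhood maximum correlation and its argmax partner.

    ``table`` rows are aligned with the source direction's neighborhoods:
    columns ``index_cell``, ``max_corr``, ``partner`` (partner index-cell ID,
    or None when every entry is undefined) and ``defined``.
    """

    table: pd.DataFrame
    direction: str  # "a_to_b" or "b_to_a"


@dataclass
class SmoothingConfig:
    """Moving-average window (odd, default 49 cells) and scaling mode."""

    window: int = 49
    scaling: str = "minmax"  # or "zscore"

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.scaling not in ("minmax", "zscore"):
            raise ValueError("scaling must be 'minmax' or 'zscore'")


def neighborhood_means(
    dataset: ExpressionDataset, nhoods: NeighborhoodSet, features: list[str]
) -> NeighborhoodProfileMatrix:
    """Mean log-normalized expression of ``features`` within each neighborhood."""
    layer = dataset.require_log_layer()
    col = {g: i for i, g in enumerate(dataset.gene_ids)}
    missing = [g for g in features if g not in col]
    if missing:
        raise ValueError(f"features absent from dataset: {missing[:5]}")
    row = {c: i for i, c in enumerate(dataset.cell_ids)}
    sub = np.asarray(layer[:, [col[g] for g in features]].todense(), dtype=float)
    values = np.empty((nhoods.N, len(features)))
    for i, members in enumerate(nhoods.members):
        try:
            rows = [row[c] for c in members]
        except KeyError as exc:
            raise ValueError(f"neighborhood references unknown cell ID {exc}") from exc
        values[i] = sub[rows].mean(axis=0)
    return NeighborhoodProfileMatrix(values, list(nhoods.index_cells), list(features))


def gene_specificity(profiles: NeighborhoodProfileMatrix) -> SpecificityMatrix:
    """Scale each gene's profile by its mean over neighborhoods.

    Genes whose sum over neighborhoods is zero are dropped (the division is
    undefined) and recorded in ``dropped_genes``.
    """
    if profiles.values.shape[0] < 2:
        raise ValueError("specificity requires at least 2 neighborhoods")
    means = profiles.values.mean(axis=0)
    keep = means > 0
    dropped = [g for g, k in zip(profiles.gene_ids, keep) if not k]
    values = profiles.values[:, keep] / means[keep]
    kept_genes = [g for g, k in zip(profiles.gene_ids, keep) if k]
    return SpecificityMatrix(values, list(profiles.index_cells), kept_genes, dropped)


def cross_correlation(spec_a: SpecificityMatrix, spec_b: SpecificityMatrix) -> CrossSpeciesCorrelation:
    """Pearson correlation between every pair of A and B specificity rows.

    Both matrices must carry the same ordered shared-gene list (species-B
    gene IDs are expected to have been mapped onto the pairing order by the
    caller).  Rows with zero variance yield NaN entries, left masked.
    """
    if len(spec_a.gene_ids) != len(spec_b.gene_ids):
        raise ValueError("specificity matrices have different gene counts")
    if len(spec_a.gene_ids) < 3:
        raise ValueError("need >= 3 shared genes for correlation")
    A, B = spec_a.values, spec_b.values
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac**2).sum(axis=1))
    sb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Ac @ Bc.T) / np.outer(sa, sb)
    corr[sa == 0, :] = np.nan
    corr[:, sb == 0] = np.nan
    corr = np.clip(corr, -1.0, 1.0)  # guard fp overshoot; NaN passes through
    return CrossSpeciesCorrelation(corr, list(spec_a.index_cells), list(spec_b.index_cells))


def max_correlation(corr: CrossSpeciesCorrelation, direction: str = "a_to_b") -> MaxCorrelationMap:
    """Maximum correlation (and argmax partner) per neighborhood.

    ``direction="a_to_b"`` scans rows (each A neighborhood against all B
    neighborhoods); ``"b_to_a"`` scans columns.  Ties break to the smallest
    partner index; all-NaN rows yield a flagged missing record.
    """
    if direction not in ("a_to_b", "b_to_a"):
        raise ValueError("direction must be 'a_to_b' or 'b_to_a'")
    if corr.values.size == 0:
        raise ValueError("empty correlation matrix")
    if direction == "a_to_b":
        values, source, partner_ids = corr.values, corr.index_cells_a, corr.index_cells_b
    else:
        values, source, partner_ids = corr.values.T, corr.index_cells_b, corr.index_cells_a
    rows = []
    for i, row in enumerate(values):
        defined = ~np.isnan(row)
        if not defined.any():
            rows.append({"index_cell": source[i], "max_corr": np.nan, "partner": None, "defined": False})
            continue
        best = np.nanmax(row)
        j = int(np.flatnonzero(row == best)[0])  # smallest tied index
        rows.append({"index_cell": source[i], "max_corr": float(best), "partner": partner_ids[j], "defined": True})
    return MaxCorrelationMap(pd.DataFrame(rows), direction)


def aggregate_by_cell_type(maxmap: MaxCorrelationMap, index_cell_types: dict) -> pd.DataFrame:
    """Group max-correlation values by the cell type of each index cell.

    Returns one row per cell type — value list, count and mean — ordered by
    decreasing mean (the ranking used for ridgeline-style summaries).
    """
    rows = []
    table = maxmap.table[maxmap.table["defined"]]
    unlabeled = [c for c in table["index_cell"] if c not in index_cell_types or index_cell_types[c] == ""]
    if unlabeled:
        raise ValueError(f"unlabeled index cells: {unlabeled[:5]}")
    groups: dict[str, list[float]] = {}
    for cell, value in zip(table["index_cell"], table["max_corr"]):
        groups.setdefault(index_cell_types[cell], []).append(float(value))
    for ctype, vals in groups.items():
        rows.append({"cell_type": ctype, "values": vals, "n": len(vals), "mean_max_corr": float(np.mean(vals))})
    out = pd.DataFrame(rows).sort_values("mean_max_corr", ascending=False).reset_index(drop=True)
    return out


def bidirectional_mapping(corr: CrossSpeciesCorrelation) -> pd.DataFrame:
    """Union of A->B and B->A argmax pairs, tagged with direction.

    Reciprocal best pairs appear twice, once per direction, mirroring the
    two independent scans.
    """
    rows = []
    for direction in ("a_to_b", "b_to_a"):
        mm = max_correlation(corr, direction)
        for rec in mm.table.itertuples(index=False):
            if not rec.defined:
                continue
            if direction == "a_to_b":
                a, b = rec.index_cell, rec.partner
            else:
                a, b = rec.partner, rec.index_cell
            rows.append({"nhood_a": a, "nhood_b": b, "value": rec.max_corr, "direction": direction})
    return pd.DataFrame(rows, columns=["nhood_a", "nhood_b", "value", "direction"])


def smooth_ordered_expression(
    values: pd.DataFrame, ordering: list, config: SmoothingConfig | None = None
):
    """Moving-average smoothing along a pseudotemporal ordering, then scaling.

    ``values`` is cells x genes; ``ordering`` is a permutation of its index.
    The centered moving average truncates (shrinks) its window at the series
    ends, preserving length.  Per gene, min-max scaling maps to [0, 1]
    (z-score as the alternative for signed scores); genes constant after
    smoothing map to all-zeros and are reported.

    Returns ``(smoothed_scaled_df, constant_genes)``.
    """
    config = config or SmoothingConfig()
    if sorted(ordering) != sorted(values.index):
        raise ValueError("ordering must be a permutation of the cells")
    n = len(ordering)
    if config.window > n:
        raise ValueError("window exceeds series length")
    ordered = values.loc[ordering].to_numpy(dtype=float)
    half = config.window // 2
    smoothed = np.empty_like(ordered)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        smoothed[i] = ordered[lo:hi].mean(axis=0)
    constant = []
    out = np.zeros_like(smoothed)
    for j, gene in enumerate(values.columns):
        col = smoothed[:, j]
        if config.scaling == "minmax":
            rng = col.max() - col.min()
            if rng == 0:
                constant.append(gene)
                continue
            out[:, j] = (col - col.min()) / rng
        else:
            sd = col.std(ddof=0)
            if sd == 0:
                constant.append(gene)
                continue
            out[:, j] = (col - col.mean()) / sd
    return pd.DataFrame(out, index=list(ordering), columns=values.columns), constant
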