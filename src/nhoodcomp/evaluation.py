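"""Ground-truth evaluation of the comparison pipeline on synthetic pairs.

These helpers run the full pipeline on generated data and score it against
the generator's ground truth: partner-type recovery for shared cell types,
the correlation penalty paid by divergent types, and the exactness of the
self-comparison identity.  They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .features import FeatureSelectionConfig
from .model import NeighborhoodComparison, NeighborhoodComparisonResults
from .neighborhoods import NeighborhoodConfig
from .orthologs import OrthologTable
from .simulate import SimulationConfig, simulate_species_pair


@dataclass
class RecoveryReport:
    """Pipeline scores against the simulation's ground truth."""

    shared_type_accuracy: float  # fraction of shared-type neighborhoods whose
    # argmax partner's index cell has the matching true type
    n_shared_nhoods: int
    type_means: dict  # cell type -> mean max correlation (A->B)
    divergent_gap: float  # min shared-type mean minus max divergent-type mean
    results: NeighborhoodComparisonResults


def run_synthetic_comparison(
    sim_config: SimulationConfig, nhood_config: NeighborhoodConfig | None = None
) -> RecoveryReport:
    """Simulate a species pair, fit the comparison, and score recovery."""
    nhood_config = nhood_config or NeighborhoodConfig()
    ds_a, ds_b, orth, truth = simulate_species_pair(sim_config)
    model = NeighborhoodComparison(ds_a, ds_b, orth, nhood_config, FeatureSelectionConfig())
    results = model.fit()

    types_a = dict(zip(ds_a.cell_ids, ds_a.cell_meta["cell_type"]))
    types_b = dict(zip(ds_b.cell_ids, ds_b.cell_meta["cell_type"]))
    shared = set(sim_config.shared_types)
    n_ok = n_tot = 0
    for rec in results.max_a_to_b.table.itertuples(index=False):
        if not rec.defined or types_a[rec.index_cell] not in shared:
            continue
        n_tot += 1
        n_ok += types_b[rec.partner] == types_a[rec.index_cell]
    accuracy = n_ok / n_tot if n_tot else float("nan")

    type_means = dict(
        zip(results.celltype_summary_a["cell_type"], results.celltype_summary_a["mean_max_corr"])
    )
    shared_means = [m for t, m in type_means.items() if t in shared]
    div_means = [m for t, m in type_means.items() if t in set(sim_config.divergent_types)]
    gap = (min(shared_means) - max(div_means)) if shared_means and div_means else float("nan")
    return RecoveryReport(accuracy, n_tot, type_means, gap, results)


def run_self_comparison(
    sim_config: SimulationConfig, nhood_config: NeighborhoodConfig | None = None
):
    """Compare a dataset against itself under identity orthology.

    Returns ``(max_abs_deviation_from_one, all_partners_self, results)``:
    every neighborhood must recover itself with correlation exactly 1.
    """
    nhood_config = nhood_config or NeighborhoodConfig()
    ds_a, _, _, _ = simulate_species_pair(sim_config)
    identity = OrthologTable(
        pd.DataFrame(
            {"gene_a": ds_a.gene_ids, "gene_b": ds_a.gene_ids, "homology_type": "one2one"}
        )
    )
    model = NeighborhoodComparison(ds_a, ds_a, identity, nhood_config, FeatureSelectionConfig())
    results = model.fit()
    tab = results.max_a_to_b.table
    deviation = float(np.abs(tab["max_corr"].to_numpy() - 1.0).max())
    partners_self = bool((tab["index_cell"] == tab["partner"]).all())
    return deviation, partners_self, results
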