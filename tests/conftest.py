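import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nhoodcomp import (
    ExpressionDataset,
    OrthologTable,
    SimulationConfig,
    log_normalize,
    simulate_gene_models,
    simulate_species_pair,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated species pair shared across tests."""
    cfg = SimulationConfig(n_cells_per_type=60, n_genes=400, seed=1)
    ds_a, ds_b, orth, truth = simulate_species_pair(cfg)
    log_normalize(ds_a)
    log_normalize(ds_b)
    return cfg, (ds_a, ds_b, orth, truth)


@pytest.fixture(scope="session")
def toy_models():
    return simulate_gene_models(n_genes=30, gene_length=1000, spacing=5000, n_chroms=2, seed=0)


@pytest.fixture()
def tiny_dataset():
    """4 cells x 3 genes with a log layer, hand-checkable."""
    counts = np.array([[2, 0, 1], [4, 0, 3], [1, 1, 1], [0, 2, 4]])
    meta = pd.DataFrame(
        {"species": "A", "stage": "S1", "cell_type": ["t1", "t1", "t2", "t2"]},
        index=[f"c{i}" for i in range(4)],
    )
    ds = ExpressionDataset(counts, ["g1", "g2", "g3"], [f"c{i}" for i in range(4)], meta)
    return log_normalize(ds)


@pytest.fixture()
def identity_orthologs():
    def make(gene_ids):
        return OrthologTable(
            pd.DataFrame({"gene_a": gene_ids, "gene_b": gene_ids, "homology_type": "one2one"})
        )

    return make
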