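"""Ortholog table between two species' gene ID spaces.

Cross-species comparison is only meaningful over genes whose homology is
unambiguous, so downstream stages restrict themselves to the ``one2one``
rows; the table nevertheless records ``one2many``/``many2many`` pairs so the
filter is explicit rather than implied by table construction.
"""

from __future__ import annotations

import pandas as pd

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")
COLUMNS = ("gene_a", "gene_b", "homology_type")


class OrthologTable:
    """Rows of ``(gene_a, gene_b, homology_type)`` with no duplicate pairs."""

    def __init__(self, table: pd.DataFrame):
        table = pd.DataFrame(table, columns=list(COLUMNS)).astype(str)
        bad = set(table["homology_type"]) - set(HOMOLOGY_TYPES)
        if bad:
            raise ValueError(f"unknown homology types: {sorted(bad)}")
        if table.duplicated(["gene_a", "gene_b"]).any():
            raise ValueError("duplicate (gene_a, gene_b) pairs")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def one2one(self) -> pd.DataFrame:
        """The one-to-one subset, the only homology class used for correlation."""
        return self.table[self.table["homology_type"] == "one2one"].reset_index(drop=True)

    def one2one_mapping(self) -> dict[str, str]:
        """gene_a -> gene_b over one2one rows."""
        sub = self.one2one()
        return dict(zip(sub["gene_a"], sub["gene_b"]))


def read_ortholog_table(path) -> OrthologTable:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"ortholog table missing columns: {sorted(missing)}")
    return OrthologTable(table[list(COLUMNS)])


def write_ortholog_table(orthologs: OrthologTable, path) -> None:
    orthologs.table.to_csv(path, sep="\t", index=False)
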