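"""Strand-aware gene models (GTF dialect), read loci and alignment intervals.

Coordinates are 1-based inclusive throughout, the GTF convention; any
half-open arithmetic stays internal to individual functions.  The writer
emits 9-column records with ``gene_id``/``transcript_id`` attributes plus an
optional ``source`` attribute used to tag synthetic extension records, and
the reader reports malformed lines with their line numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FEATURE_TYPES = ("gene", "transcript", "exon", "CDS")
STRANDS = ("+", "-")
REGION_CLASSES = ("exonic", "intronic", "intergenic")

MODEL_COLUMNS = ("feature_type", "chrom", "start", "end", "strand", "gene_id", "transcript_id", "source_tag")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GeneModelSet:
    """A validated set of gene/transcript/exon/CDS interval records."""

    def __init__(self, records: pd.DataFrame):
        df = pd.DataFrame(records, columns=list(MODEL_COLUMNS))
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        for col in ("feature_type", "chrom", "strand", "gene_id", "transcript_id", "source_tag"):
            df[col] = df[col].fillna("").astype(str)
        bad_type = set(df["feature_type"]) - set(FEATURE_TYPES)
        if bad_type:
            raise ValueError(f"unknown feature types: {sorted(bad_type)}")
        bad_strand = set(df["strand"]) - set(STRANDS)
        if bad_strand:
            raise ValueError(f"invalid strands: {sorted(bad_strand)}")
        if (df["start"] < 1).any():
            raise ValueError("coordinates are 1-based; start < 1")
        if (df["end"] < df["start"]).any():
            i = df.index[df["end"] < df["start"]][0]
            raise ValueError(f"record {i}: end < start")
        self.records = df.reset_index(drop=True)
        self._check_exons_within_genes()

    def _check_exons_within_genes(self) -> None:
        genes = self.gene_records().set_index("gene_id")
        sub = self.records[self.records["feature_type"].isin(("exon", "CDS"))]
        for _, rec in sub.iterrows():
            gid = rec["gene_id"]
            if gid in genes.index:
                g = genes.loc[gid]
                if rec["start"] < g["start"] or rec["end"] > g["end"]:
                    raise ValueError(
                        f"{rec['feature_type']} [{rec['start']},{rec['end']}] of {gid} "
                        f"outside gene span [{g['start']},{g['end']}]"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def gene_records(self) -> pd.DataFrame:
        return self.records[self.records["feature_type"] == "gene"].reset_index(drop=True)

    def gene_ids(self) -> list[str]:
        return self.gene_records()["gene_id"].tolist()

    def three_prime_ends(self) -> pd.DataFrame:
        """Per gene: chrom, strand and the 3'-most annotated coordinate.

        On the + strand the 3' end is the gene's ``end``; on the - strand it
        is the gene's ``start``.
        """
        genes = self.gene_records()
        pos = np.where(genes["strand"] == "+", genes["end"], genes["start"])
        return pd.DataFrame(
            {
                "gene_id": genes["gene_id"],
                "chrom": genes["chrom"],
                "strand": genes["strand"],
                "three_prime": pos.astype(np.int64),
            }
        )

    def exon_records(self) -> pd.DataFrame:
        return self.records[self.records["feature_type"] == "exon"].reset_index(drop=True)

    def copy(self) -> "GeneModelSet":
        return GeneModelSet(self.records.copy())

    def record_set(self) -> set[tuple]:
        """Hashable record set for order-insensitive equality checks."""
        return set(map(tuple, self.records[list(MODEL_COLUMNS)].itertuples(index=False, name=None)))

    def equals(self, other: "GeneModelSet") -> bool:
        return self.record_set() == other.record_set()


@dataclass(frozen=True)
class ReadLocus:
    """A single aligned read position with its annotation region class."""

    chrom: str
    position: int  # 1-based
    strand: str
    region_class: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"invalid region class {self.region_class!r}")


@dataclass(frozen=True)
class AlignmentInterval:
    """One aligned segment of a query transcript on the target genome."""

    query_transcript_id: str
    target_chrom: str
    target_start: int
    target_end: int
    target_strand: str
    score: float

    def __post_init__(self):
        if self.target_end < self.target_start:
            raise ValueError("target_end < target_start")
        if self.target_strand not in STRANDS:
            raise ValueError(f"invalid strand {self.target_strand!r}")


# -- GTF I/O ------------------------------------------------------------


def read_gtf(path) -> GeneModelSet:
    """Parse a GTF file into a :class:`GeneModelSet`.

    Only gene/transcript/exon/CDS features are retained.  Malformed lines
    raise ``ValueError`` carrying the 1-based line number.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
        if feature not in FEATURE_TYPES:
            continue
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
        if end_i < start_i:
            raise ValueError(f"{path}:{lineno}: end < start")
        if strand not in STRANDS:
            raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
        attr = dict(_ATTR_RE.findall(attrs))
        rows.append(
            {
                "feature_type": feature,
                "chrom": chrom,
                "start": start_i,
                "end": end_i,
                "strand": strand,
                "gene_id": attr.get("gene_id", ""),
                "transcript_id": attr.get("transcript_id", ""),
                "source_tag": attr.get("source", ""),
            }
        )
    return GeneModelSet(pd.DataFrame(rows, columns=list(MODEL_COLUMNS)))


def write_gtf(models: GeneModelSet, path) -> None:
    lines = []
    for rec in models.records.itertuples(index=False):
        attrs = f'gene_id "{rec.gene_id}";'
        if rec.transcript_id:
            attrs += f' transcript_id "{rec.transcript_id}";'
        if rec.source_tag:
            attrs += f' source "{rec.source_tag}";'
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    "nhoodcomp",
                    rec.feature_type,
                    str(rec.start),
                    str(rec.end),
                    ".",
                    rec.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


# -- read-locus and alignment tables ------------------------------------

_READ_COLUMNS = ["chrom", "position", "strand", "region_class"]
_ALN_COLUMNS = ["query_transcript_id", "target_chrom", "target_start", "target_end", "target_strand", "score"]


def read_read_loci(path) -> list[ReadLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(_READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read-locus table missing columns: {sorted(missing)}")
    return [
        ReadLocus(str(r.chrom), int(r.position), str(r.strand), str(r.region_class))
        for r in df.itertuples(index=False)
    ]


def write_read_loci(reads: list[ReadLocus], path) -> None:
    pd.DataFrame([r.__dict__ for r in reads], columns=_READ_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignments(path) -> list[AlignmentInterval]:
    df = pd.read_csv(path, sep="\t", dtype={"target_chrom": str})
    missing = set(_ALN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    return [
        AlignmentInterval(
            str(r.query_transcript_id),
            str(r.target_chrom),
            int(r.target_start),
            int(r.target_end),
            str(r.target_strand),
            float(r.score),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignments(alignments: list[AlignmentInterval], path) -> None:
    pd.DataFrame([a.__dict__ for a in alignments], columns=_ALN_COLUMNS).to_csv(path, sep="\t", index=False)
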