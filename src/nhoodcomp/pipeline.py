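"""End-to-end orchestration with manifesting and a single fan-out seed.

``run_full_comparison`` executes normalize -> embed -> graph -> neighborhoods
(per species) -> feature selection -> profiles -> specificity -> correlation
-> max/aggregation/pairs, writes every intermediate as a re-loadable text
artifact, and records a manifest (package version, seed, parameters,
per-file SHA-256 checksums) so a run is reproducible from one number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .datasets import read_counts
from .features import FeatureSelectionConfig
from .model import NeighborhoodComparison
from .neighborhoods import NeighborhoodConfig
from .orthologs import read_ortholog_table
from .simulate import SimulationConfig, simulate_species_pair

logger = logging.getLogger("nhoodcomp")


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from one run seed."""
    return (int(seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full comparison run.

    Either ``simulation`` (a SimulationConfig) or the six per-species input
    paths (+ ortholog table path) must be provided.
    """

    output_dir: str = "nhoodcomp_run"
    seed: int = 0
    log_level: str = "INFO"
    # input option 1: synthetic pair
    simulation: SimulationConfig | None = None
    # input option 2: on-disk matrices
    counts_a: str | None = None
    genes_a: str | None = None
    cells_a: str | None = None
    meta_a: str | None = None
    counts_b: str | None = None
    genes_b: str | None = None
    cells_b: str | None = None
    meta_b: str | None = None
    orthologs: str | None = None
    # stage parameters (defaults are the published study's values)
    k: int = 30
    n_pcs: int = 50
    n_hvgs: int = 2000
    sampling_proportion: float = 0.05
    n_top_features: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_nhoods(nhoods, path: Path) -> None:
    payload = [
        {"index_cell": idx, "members": sorted(members)}
        for idx, members in zip(nhoods.index_cells, nhoods.members)
    ]
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def run_full_comparison(config: PipelineConfig) -> dict:
    """Run the full pipeline and return the output manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim = config.simulation
        sim_seed = derive_seed(config.seed, "simulate")
        sim = SimulationConfig(**{**asdict(sim), "seed": sim_seed})
        logger.info("simulating species pair (seed %d)", sim_seed)
        ds_a, ds_b, orthologs, _truth = simulate_species_pair(sim)
    else:
        required = [config.counts_a, config.genes_a, config.cells_a, config.counts_b, config.genes_b, config.cells_b, config.orthologs]
        if any(p is None for p in required):
            raise ValueError("either 'simulation' or all input paths must be set")
        ds_a = read_counts(config.counts_a, config.genes_a, config.cells_a, config.meta_a)
        ds_b = read_counts(config.counts_b, config.genes_b, config.cells_b, config.meta_b)
        orthologs = read_ortholog_table(config.orthologs)

    nhood_cfg = NeighborhoodConfig(
        k=config.k,
        n_pcs=config.n_pcs,
        n_hvgs=config.n_hvgs,
        sampling_proportion=config.sampling_proportion,
        seed=derive_seed(config.seed, "neighborhoods"),
    )
    feat_cfg = FeatureSelectionConfig(n_top=config.n_top_features)
    model = NeighborhoodComparison(ds_a, ds_b, orthologs, nhood_cfg, feat_cfg)
    logger.info("fitting neighborhood comparison")
    results = model.fit()

    import pandas as pd

    files = {}

    def _save(name, writer):
        path = outdir / name
        writer(path)
        files[name] = _sha256(path)

    _save("features.tsv", lambda p: results.features.to_csv(p, sep="\t", index=False))
    corr_df = pd.DataFrame(
        results.correlation.values,
        index=results.correlation.index_cells_a,
        columns=results.correlation.index_cells_b,
    )
    _save("correlation.tsv", lambda p: corr_df.to_csv(p, sep="\t", index_label="nhood_a"))
    _save("max_a_to_b.tsv", lambda p: results.max_a_to_b.table.to_csv(p, sep="\t", index=False))
    _save("max_b_to_a.tsv", lambda p: results.max_b_to_a.table.to_csv(p, sep="\t", index=False))
    for name, summary in (
        ("celltype_summary_a.tsv", results.celltype_summary_a),
        ("celltype_summary_b.tsv", results.celltype_summary_b),
    ):
        flat = summary.drop(columns=["values"])
        _save(name, lambda p, flat=flat: flat.to_csv(p, sep="\t", index=False))
    _save("pairs.tsv", lambda p: results.pairs.to_csv(p, sep="\t", index=False))
    _save("nhoods_a.json", lambda p: _write_nhoods(results.nhoods_a, p))
    _save("nhoods_b.json", lambda p: _write_nhoods(results.nhoods_b, p))
    _save("summary.txt", lambda p: p.write_text(results.summary() + "\n"))

    from . import __version__

    manifest = {
        "package": "nhoodcomp",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "k": config.k,
            "n_pcs": config.n_pcs,
            "n_hvgs": config.n_hvgs,
            "sampling_proportion": config.sampling_proportion,
            "n_top_features": config.n_top_features,
            "simulation": asdict(config.simulation) if config.simulation else None,
        },
        "n_neighborhoods_a": results.nhoods_a.N,
        "n_neighborhoods_b": results.nhoods_b.N,
        "n_features": len(results.features),
        "checksums": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run complete: %s", outdir / "manifest.json")
    return manifest
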