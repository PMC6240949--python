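"""Configuration-driven orchestration of the full analysis.

A :class:`PipelineConfig` (loadable from YAML) names the inputs, the QC
thresholds, the stage toggles and the global seed; :func:`run` executes the
enabled stages in QC -> dataset construction -> statistics order and writes
tab-separated report tables, a QC report, a run log and a machine-readable
manifest into the output directory.  Per-stage sub-seeds are derived from
the global seed by hashing the stage name, so toggling one stage never
shifts another stage's random stream.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amova import HierarchyAssignment, amova
from .differentiation import fst_matrix, nj_tree, reynolds_matrix
from .diversity import diversity_table
from .genotype_io import (
    GenotypeDataset,
    attach_metadata,
    read_plink_text,
    write_metadata,
    write_plink_text,
)
from .kinship_mds import individual_mds, population_mds
from .ld import ld_scan, ne_from_ld, sharing_distribution
from .qc import QCThresholds, apply_qc
from .simdata import SimConfig, simulate_dataset

logger = logging.getLogger("caprapop")

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str = "caprapop_out"
    ped: str | None = None
    map: str | None = None
    metadata: str | None = None
    simulate: dict | None = None
    thresholds: dict = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)
    continent_of_population: dict[str, str] | None = None
    drop_populations: list[str] = field(default_factory=list)
    stages: list[str] = field(
        default_factory=lambda: [
            "qc", "diversity", "fst", "reynolds", "amova", "mds", "ld", "ne",
        ]
    )
    n_perm: int = 0
    ld_r2_min: float = 0.3
    ld_max_dist_bp: int = 10_000_000
    ne_sample_size: int = 22

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def build_continental_datasets(
    ds: GenotypeDataset,
    grouping: dict[str, str] | None = None,
    drop: list[str] | None = None,
) -> dict[str, GenotypeDataset]:
    """Per-continent subsets plus the union of the grouped continents.

    ``grouping`` maps population -> continent; None uses the samples'
    continent metadata.  Populations missing from the grouping are an
    error unless listed in ``drop``.  Sample and variant order are
    preserved in every subset.
    """
    drop = set(drop or [])
    pops = list(ds.population_indices())
    if grouping is None:
        grouping = {}
        for s in ds.samples:
            grouping.setdefault(s.population, s.continent)
    missing = [p for p in pops if p not in grouping and p not in drop]
    if missing:
        raise ValueError(f"populations without continent assignment: {missing}")
    continents: dict[str, list[str]] = {}
    for p in pops:
        if p in drop:
            continue
        continents.setdefault(grouping[p], []).append(p)
    out: dict[str, GenotypeDataset] = {}
    union_pops: list[str] = []
    for cont, members in continents.items():
        out[cont] = ds.select_populations(members)
        union_pops += members
    out["combined"] = ds.select_populations(union_pops)
    return out


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dictionary."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": dict(config.thresholds),
        "outputs": [],
    }

    def _register(path: Path) -> None:
        manifest["outputs"].append(path.name)

    try:
        ds = _load_or_simulate(config, out_dir, _register)
        logger.info(
            "input: %d samples, %d variants, %d populations",
            ds.n_samples, ds.n_variants, len(ds.population_indices()),
        )
        thr = QCThresholds(**config.thresholds)

        if "qc" in config.stages:
            ds, report = apply_qc(
                ds, thr, exclusions=config.exclusions,
                seed=stage_seed(config.seed, "qc"),
            )
            _write_tsv(report.to_frame(), out_dir / "qc_removals.tsv")
            _write_tsv(report.stage_frame(), out_dir / "qc_stages.tsv")
            _register(out_dir / "qc_removals.tsv")
            _register(out_dir / "qc_stages.tsv")
            logger.info("post-QC: %d samples, %d variants", ds.n_samples, ds.n_variants)

        if "diversity" in config.stages:
            tab = diversity_table(
                ds, n_perm=config.n_perm, seed=stage_seed(config.seed, "diversity")
            )
            _write_tsv(tab, out_dir / "diversity.tsv")
            _register(out_dir / "diversity.tsv")

        if "fst" in config.stages:
            pm = fst_matrix(
                ds, n_perm=config.n_perm, seed=stage_seed(config.seed, "fst")
            )
            _write_tsv(pm.to_frame(floor_zero=True), out_dir / "fst_matrix.tsv", index=True)
            _register(out_dir / "fst_matrix.tsv")
            if pm.pvalues is not None:
                _write_tsv(
                    pd.DataFrame(pm.pvalues, index=pm.labels, columns=pm.labels),
                    out_dir / "fst_pvalues.tsv", index=True,
                )
                _register(out_dir / "fst_pvalues.tsv")

        if "reynolds" in config.stages:
            rm = reynolds_matrix(ds)
            _write_tsv(rm.to_frame(), out_dir / "reynolds_matrix.tsv", index=True)
            (out_dir / "reynolds.phy").write_text(rm.to_phylip())
            _register(out_dir / "reynolds_matrix.tsv")
            _register(out_dir / "reynolds.phy")
            if len(rm.labels) >= 3:
                (out_dir / "nj_tree.nwk").write_text(nj_tree(rm) + "\n")
                _register(out_dir / "nj_tree.nwk")

        if "amova" in config.stages:
            res3 = amova(ds, levels=3)
            _write_tsv(res3.to_frame(), out_dir / "amova_3level.tsv")
            _register(out_dir / "amova_3level.tsv")
            manifest["amova_3level_phi"] = res3.phi
            n_groups = len({s.continent for s in ds.samples})
            if n_groups >= 2:
                res4 = amova(
                    ds, HierarchyAssignment.from_dataset(ds, use_continent_groups=True),
                    levels=4,
                )
                _write_tsv(res4.to_frame(), out_dir / "amova_4level.tsv")
                _register(out_dir / "amova_4level.tsv")
                manifest["amova_4level_phi"] = res4.phi

        if "mds" in config.stages:
            mi = individual_mds(ds, k=3)
            tab = mi.to_frame()
            tab["population"] = [s.population for s in ds.samples]
            tab["continent"] = [s.continent for s in ds.samples]
            _write_tsv(tab, out_dir / "mds_individuals.tsv")
            _register(out_dir / "mds_individuals.tsv")
            if len(ds.population_indices()) >= 3:
                mp = population_mds(ds, k=3)
                _write_tsv(mp.to_frame(), out_dir / "mds_populations.tsv")
                _register(out_dir / "mds_populations.tsv")
                manifest["mds_population_variance_fraction"] = [
                    float(v) for v in mp.variance_fraction
                ]

        if "ld" in config.stages:
            pair_sets = {
                pop: ld_scan(
                    ds, pop, max_dist_bp=config.ld_max_dist_bp,
                    r2_min=config.ld_r2_min,
                )
                for pop in ds.population_indices()
            }
            continent_of = {s.population: s.continent for s in ds.samples}
            shares = sharing_distribution(pair_sets, continent_of)
            for cont, sd in shares.items():
                path = out_dir / f"ld_sharing_{cont}.tsv"
                _write_tsv(sd.histogram, path)
                _register(path)
            manifest["ld_sharing_mode"] = {c: s.mode_k for c, s in shares.items()}

        if "ne" in config.stages:
            for pop in ds.population_indices():
                traj = ne_from_ld(
                    ds, pop, sample_size=config.ne_sample_size,
                    seed=stage_seed(config.seed, f"ne:{pop}"),
                )
                if traj is None:
                    logger.info("ne: population %s below sample size, skipped", pop)
                    continue
                path = out_dir / f"ne_trajectory_{pop}.tsv"
                _write_tsv(traj, path)
                _register(path)
    except Exception as exc:
        logger.error("stage failure: %s", exc)
        logger.removeHandler(handler)
        handler.close()
        raise

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %d outputs", len(manifest["outputs"]))
    logger.removeHandler(handler)
    handler.close()
    return manifest


def _load_or_simulate(config: PipelineConfig, out_dir: Path, register) -> GenotypeDataset:
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
        cfg = SimConfig(**sim_kwargs)
        ds = simulate_dataset(cfg)
        ped, mp = write_plink_text(ds, out_dir / "simulated")
        meta = write_metadata(ds, out_dir / "simulated_metadata.tsv")
        with open(out_dir / "sim_config.json", "w") as fh:
            json.dump(dataclasses.asdict(cfg), fh, indent=2, sort_keys=True)
        for p in (ped, mp, meta, out_dir / "sim_config.json"):
            register(p)
        return ds
    if not config.ped or not config.map:
        raise ValueError("config needs either 'simulate' or ped/map paths")
    ds = read_plink_text(config.ped, config.map)
    if config.metadata:
        ds, unmatched = attach_metadata(ds, config.metadata)
        if unmatched:
            logger.warning("samples without metadata: %s", unmatched)
    return ds
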