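"""End-to-end orchestration: simulate -> filter -> scan -> cluster -> MGV ->
epistasis -> line scores, with a reproducible run manifest.

Two modes mirror how the data flow in a tail-selection study.  *Simulate*
runs the forward simulator under a configured architecture and writes the
three exchange tables (line-level genotype matrix after the plant-level
call-rate filter, plant-level phenotypes, marker map) plus the ground
truth.  *Analyze* consumes those tables — or any user-supplied tables in
the same formats — and runs the statistical cascade, writing one TSV per
stage and a JSON manifest recording configuration, seed and output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import epistasis as _epi
from . import io as _io
from . import preset as _preset
from . import sim as _sim
from . import stats as _stats

log = logging.getLogger("transseg")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serialisable to YAML."""

    mode: str = "simulate"                    # "simulate" or "analyze"
    out_dir: str = "transseg_out"
    seed: int = 0
    # analyze-mode inputs
    genotypes: str | None = None
    phenotypes: str | None = None
    marker_map: str | None = None
    # thresholds
    min_call_rate: float = 0.8
    alpha: float = 0.05
    max_span_mb: float = 3.5
    min_cluster_size: int = 2
    scope: str = "either_population"
    n_perm: int = 1999
    n_top_loci: int = 6        # strongest representatives used for epistasis
                               # scan and MGV-weighted line scoring
    # years
    years: list[int] = field(default_factory=lambda: [2015, 2016])
    primary_year: int = 2015
    selection_year: int = 2014

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.min_call_rate <= 1):
            raise ValueError("min_call_rate must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.max_span_mb <= 0:
            raise ValueError("max_span_mb must be positive")
        if self.mode == "analyze":
            for name in ("genotypes", "phenotypes", "marker_map"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"analyze mode requires existing {name} path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class StudyData:
    """Simulated study inputs plus ground truth."""

    genotypes: _io.GenotypeMatrix        # line level, call-rate filtered
    plant_genotypes: _io.GenotypeMatrix  # plant level, unfiltered
    phenotypes: _io.PhenotypeTable       # F3 selection year + F4 years
    marker_map: _io.MarkerMap
    cross: _sim.CrossSimulation


def simulate_study(architecture: _sim.QTLArchitecture,
                   config: _sim.CrossConfig,
                   marker_map: _io.MarkerMap | None = None,
                   years: list[int] | None = None,
                   selection_year: int | None = None,
                   min_call_rate: float = 0.8) -> StudyData:
    """Run the study design and produce analysis-ready tables.

    F4 lines are genotyped plant by plant with random dropout; markers
    called in fewer than ``min_call_rate`` of the plants are removed (the
    reliability filter), and the survivors are collapsed to line-level
    consensus calls.  Phenotypes cover the F3 selection year for the
    selected lines and every requested F4 year.
    """
    rng = np.random.default_rng(config.rng_seed)
    if marker_map is None:
        n = config.markers_per_chromosome
        if n is None:
            raise ValueError("either marker_map or markers_per_chromosome required")
        marker_map = _sim.random_marker_map(
            _preset.RICE_CHROM_LENGTHS_CM, n, rng, bp_per_cm=config.bp_per_cm)
    cross = _sim.simulate_pedigree(architecture, config, marker_map,
                                   selection_year=selection_year)
    sel_year = selection_year if selection_year is not None \
        else min(architecture.year_effects)
    if years is None:
        years = [y for y in sorted(architecture.year_effects) if y > sel_year]

    pops = {l.line_id: cross.population_of(l.line_id) for l in cross.f4_lines}
    plant_gm = _sim.genotype_markers(
        cross.f4_lines, cross.layout, config.missing_call_rate,
        rng, populations=pops, n_plants=config.plants_genotyped_per_line)
    filtered = _stats.call_rate_filter(plant_gm, min_call_rate)
    line_gm = _sim.consensus_genotypes(filtered)

    selected = set(pops)
    phen = _io.PhenotypeTable(cross.f3_phenotypes.data[
        cross.f3_phenotypes.data["line"].isin(selected)])
    rng_phen = np.random.default_rng(rng.integers(0, 2**31))
    for year in years:
        phen = phen.concat(_sim.assign_phenotypes(
            cross.f4_lines, cross.layout, architecture, year, rng_phen,
            n_plants=config.plants_phenotyped_per_line))
    return StudyData(genotypes=line_gm, plant_genotypes=plant_gm,
                     phenotypes=phen, marker_map=marker_map, cross=cross)


@dataclass
class ResultBundle:
    """Outputs of one analysis run."""

    genotypes: _io.GenotypeMatrix
    scan: _stats.DistortionScan
    clusters: _cluster.ClusterSet
    mgv_tables: dict[int, pd.DataFrame]
    representatives: list[str]
    interactions: pd.DataFrame | None
    line_scores: _stats.LineScores | None
    manifest: dict[str, Any]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:   # noqa: BLE001 - named stage failure
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def analyze_tables(gm: _io.GenotypeMatrix, phen: _io.PhenotypeTable,
                   marker_map: _io.MarkerMap, cfg: RunConfig) -> ResultBundle:
    """Run the statistical cascade on in-memory tables."""
    gm_f = _stage("call_rate_filter")(_stats.call_rate_filter)(
        gm, cfg.min_call_rate)
    scan = _stage("distortion_scan")(_stats.distortion_scan)(
        gm_f, alpha=cfg.alpha, scope=cfg.scope)
    present = [m for m in scan.flagged if m in marker_map]
    clusters = _stage("cluster_snps")(_cluster.cluster_snps)(
        present, marker_map, max_span=cfg.max_span_mb * 1e6,
        min_size=cfg.min_cluster_size)

    years = [y for y in cfg.years if y in phen.years]
    mgv_tables: dict[int, pd.DataFrame] = {}
    cluster_members = [m for c in clusters.clusters for m in c.members]
    for year in years:
        mgv_tables[year] = _stage("mgv")(_stats.mgv_table)(
            gm_f, phen, cluster_members or present, year)

    representatives: list[str] = []
    top: list[str] = []
    interactions = None
    line_scores = None
    primary = cfg.primary_year if cfg.primary_year in years else \
        (years[0] if years else None)
    if primary is not None and clusters.clusters:
        _stage("representatives")(_cluster.assign_representatives)(
            clusters, mgv_tables[primary], primary)
        representatives = [c.representative for c in clusters.clusters]
        # focus downstream two-locus work and line scoring on the strongest
        # candidate loci, mirroring the handful of loci a study would carry
        # forward; requiring homozygosity at every one of dozens of
        # representatives would leave no eligible line
        by_mgv = mgv_tables[primary].set_index("marker")["mgv"]
        top = sorted(representatives, key=lambda m: -by_mgv.get(m, 0.0))
        top = top[: cfg.n_top_loci]
        if len(top) >= 2:
            rng = np.random.default_rng(cfg.seed + 1)
            interactions, _ = _stage("interaction_scan")(_epi.interaction_scan)(
                gm_f, phen, top, primary, n_perm=cfg.n_perm, rng=rng)
        recs = {m: _stats.mgv(gm_f, phen, m, primary) for m in top}
        if top and all(r.is_testable for r in recs.values()):
            line_scores = _stage("score_lines")(_stats.score_lines)(
                gm_f, recs, top, phen, primary)

    manifest: dict[str, Any] = {
        "config": cfg.to_dict(),
        "n_markers_input": gm.n_markers,
        "n_markers_filtered": gm_f.n_markers,
        "n_flagged": len(scan.flagged),
        "n_clusters": len(clusters.clusters),
        "representatives": representatives,
        "top_loci": top,
    }
    return ResultBundle(genotypes=gm_f, scan=scan, clusters=clusters,
                        mgv_tables=mgv_tables, representatives=representatives,
                        interactions=interactions, line_scores=line_scores,
                        manifest=manifest)


def run_analysis(cfg: RunConfig,
                 architecture: _sim.QTLArchitecture | None = None,
                 cross_config: _sim.CrossConfig | None = None) -> ResultBundle:
    """Run one configured pipeline and write all outputs + manifest.

    In simulate mode the study preset is used unless an explicit
    architecture and cross design are supplied; the seed in ``cfg``
    overrides the cross design's seed so one number reproduces the run.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "simulate":
        if architecture is None or cross_config is None:
            architecture, cross_config = _preset.study_preset(seed=cfg.seed)
        cross_config = dataclasses.replace(cross_config, rng_seed=cfg.seed)
        data = _stage("simulate")(simulate_study)(
            architecture, cross_config, years=cfg.years,
            selection_year=cfg.selection_year,
            min_call_rate=cfg.min_call_rate)
        gm, phen, mmap = data.genotypes, data.phenotypes, data.marker_map
        _io.write_genotypes(gm, out / "genotypes.tsv",
                            header_comments=[f"seed={cfg.seed}"])
        _io.write_phenotypes(phen, out / "phenotypes.tsv",
                             header_comments=[f"seed={cfg.seed}"])
        _io.write_map(mmap, out / "marker_map.tsv",
                      header_comments=[f"seed={cfg.seed}"])
    else:
        gm = _io.read_genotypes(cfg.genotypes)
        phen = _io.read_phenotypes(cfg.phenotypes)
        mmap = _io.read_map(cfg.marker_map)

    bundle = analyze_tables(gm, phen, mmap, cfg)

    _write_tsv(bundle.scan.table, out / "distortion.tsv")
    _write_tsv(bundle.clusters.to_frame(), out / "clusters.tsv")
    for year, table in bundle.mgv_tables.items():
        _write_tsv(table, out / f"mgv_{year}.tsv")
    if bundle.interactions is not None:
        _write_tsv(bundle.interactions, out / "interactions.tsv")
    if bundle.line_scores is not None:
        _write_tsv(bundle.line_scores.table, out / "line_scores.tsv")

    outputs = sorted(p for p in out.iterdir()
                     if p.suffix in (".tsv",) and p.is_file())
    bundle.manifest["outputs"] = {p.name: _sha256(p) for p in outputs}
    if bundle.line_scores is not None:
        bundle.manifest["spearman_rho"] = bundle.line_scores.spearman_rho
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True, default=str)
    return bundle
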