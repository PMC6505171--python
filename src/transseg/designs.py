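"""Ready-made small experimental designs built on the simulator.

Calibration and recovery experiments used throughout the documentation and
tests: an F2 mapping population genotyped directly at its trait loci, a
fully unlinked null population for scan calibration, and a single-QTL
tail-selection design for power measurement.  Each returns analysis-ready
containers so an experiment is one function call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MarkerMap, PhenotypeTable
from .sim import (CrossConfig, QTLArchitecture, QTLLocus, build_parents,
                  consensus_genotypes, genotype_codes, genotype_markers,
                  phenotype_plants, self_batch, simulate_pedigree)
from .stats import distortion_scan


def locus_marker_map(architecture: QTLArchitecture) -> MarkerMap:
    """One marker co-located with every trait locus (``m_<locus_id>``)."""
    rows = [(f"m_{l.locus_id}", l.chrom, l.bp, l.cm) for l in architecture.loci]
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]))


def f2_mapping_population(architecture: QTLArchitecture, n_plants: int,
                          seed: int, year: int | None = None
                          ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """An unselected F2 population genotyped at markers on its trait loci.

    Each plant is its own 'line' (one plant per line), the setting in which
    marker genotype values estimate additive effects directly.
    """
    rng = np.random.default_rng(seed)
    mm = locus_marker_map(architecture)
    layout, p1, p2 = build_parents(architecture, mm)
    f1 = np.stack([p1[0], p2[0]])
    f2 = self_batch(f1[None], np.zeros(n_plants, int), layout, rng)
    markers = [f"m_{l.locus_id}" for l in architecture.loci]
    pos = [layout.position(m) for m in markers]
    calls = genotype_codes(f2, pos).T.astype(np.int8)
    samples = [f"P{i + 1}" for i in range(n_plants)]
    gm = GenotypeMatrix(markers, samples, calls)
    if year is None:
        year = min(architecture.year_effects)
    dth = phenotype_plants(f2, layout, architecture, year, rng)
    pt = PhenotypeTable(pd.DataFrame(
        {"line": samples, "year": year, "plant": 1, "dth": dth}))
    return gm, pt


def unlinked_null_population(n_markers: int, n_lines: int, seed: int,
                             plants_genotyped: int = 3) -> GenotypeMatrix:
    """F4 line genotypes at fully unlinked neutral markers (one/chromosome).

    No trait loci and no selection: every line descends from a random F2
    plant through unselected selfing, so any segregation distortion is pure
    sampling noise — the null for scan calibration.
    """
    rows = [(f"u{i + 1}", f"c{i + 1}", 1, 0.0) for i in range(n_markers)]
    mm = MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]))
    arch = QTLArchitecture(loci=[], epistatic_pairs=[],
                           year_effects={0: 0.0}, noise_sd=1.0)
    cfg = CrossConfig(n_f2=n_lines, n_f3_lines=n_lines,
                      plants_phenotyped_per_line=1,
                      plants_genotyped_per_line=plants_genotyped,
                      n_tail_early=0, n_tail_late=0, conditioning_locus=None,
                      missing_call_rate=0.0, rng_seed=seed)
    cross = simulate_pedigree(arch, cfg, mm)
    rng = np.random.default_rng(seed + 7)
    plant_gm = genotype_markers(cross.f4_lines, cross.layout, 0.0, rng,
                                n_plants=plants_genotyped)
    return consensus_genotypes(plant_gm)


def single_qtl_tail_design(additive: float, seed: int, noise_sd: float = 2.0,
                           n_unlinked: int = 12,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Tail-selection scan of one QTL flanked by markers within 1 cM.

    The study's selection design (248 F2, 132 F3 lines of six phenotyped
    plants, 15 + 15 tails, three genotyped F4 plants per line) applied to a
    single locus of the given additive effect; markers 0.5 cM either side
    of the locus measure power, markers on a second chromosome measure the
    false-flag rate.  Returns the scan table indexed by marker.
    """
    arch = QTLArchitecture(
        loci=[QTLLocus("qA", "1", 60.0, 18_000_000, additive, 0.0, "P2")],
        epistatic_pairs=[], baseline_dth=80.0,
        year_effects={2014: 0.0}, noise_sd=noise_sd)
    rows = [("near_1", "1", 17_850_000, 59.5), ("near_2", "1", 18_150_000, 60.5),
            ("flank_lo", "1", 1, 0.0), ("flank_hi", "1", 36_000_000, 120.0)]
    for i in range(n_unlinked):
        rows.append((f"unlinked_{i + 1}", "2", 1 + i * 3_000_000, i * 10.0))
    mm = MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]))
    cfg = CrossConfig(n_f2=248, n_f3_lines=132, plants_phenotyped_per_line=6,
                      plants_genotyped_per_line=3, n_tail_early=15,
                      n_tail_late=15, conditioning_locus=None,
                      missing_call_rate=0.0, rng_seed=seed)
    cross = simulate_pedigree(arch, cfg, mm)
    pops = {l.line_id: cross.population_of(l.line_id) for l in cross.f4_lines}
    rng = np.random.default_rng(seed + 2**20)
    plant_gm = genotype_markers(cross.f4_lines, cross.layout, 0.0, rng,
                                populations=pops, n_plants=3)
    gm = consensus_genotypes(plant_gm)
    scan = distortion_scan(gm, alpha=alpha, scope="either_population")
    return scan.table.set_index("marker")
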