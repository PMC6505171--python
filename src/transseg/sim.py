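"""Forward simulation of a biparental selfing pedigree (F1 -> F2 -> F3 -> F4).

The simulator reproduces the design of a tail-selection QTL study in a
selfing crop: two fully homozygous parents differing at a small number of
minor-effect trait loci with complementary directions are crossed; the F1 is
selfed to an F2; random F2 plants found F3 lines; the phenotypic extremes of
the F3 lines (optionally conditioned on homozygosity at one locus) are
selfed again to F4 lines which are then genotyped at a ddRAD-like marker
panel with missing calls.

Transmission is Mendelian with a Haldane (no-interference) recombination
model: the number of crossovers per chromosome per meiosis is Poisson with
mean equal to the genetic map length in Morgans, and crossover positions are
uniform on the genetic map.  Alleles are tracked as parental-origin labels
(0 = parent 1, 1 = parent 2) at every marker and trait-locus position.

The phenotype model for a plant is

    DTH = baseline + year_effect
        + sum over loci of a_l * g_l  (g_l = -1 for the shortening-parent
          homozygote, +1 for the other homozygote, 0 when heterozygous)
        + d_l for heterozygous loci
        + epistatic offsets indexed by two-locus genotype classes
        + Normal(0, noise_sd)

and a line's value is the mean over its phenotyped plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (CALL_A, CALL_B, CALL_H, CALL_NA, GenotypeMatrix, MarkerMap,
                 PhenotypeTable)

PARENT1 = "P1"
PARENT2 = "P2"


@dataclass(frozen=True)
class QTLLocus:
    """One trait locus: map position, additive effect and effect direction.

    ``additive`` is half the difference between the two homozygote class
    means, in days (a >= 0).  ``shortening_parent`` names the parent whose
    homozygote heads *earlier* at this locus.  ``dominance`` is the
    deviation of the heterozygote from the homozygote midpoint, in days.
    """

    locus_id: str
    chrom: str
    cm: float
    bp: int
    additive: float
    dominance: float = 0.0
    shortening_parent: str = PARENT2

    def __post_init__(self):
        if self.additive < 0:
            raise ValueError(f"locus {self.locus_id}: additive effect must be >= 0")
        if self.shortening_parent not in (PARENT1, PARENT2):
            raise ValueError(
                f"locus {self.locus_id}: shortening_parent must be "
                f"{PARENT1!r} or {PARENT2!r}")


@dataclass(frozen=True)
class EpistaticPair:
    """Additive phenotype offsets indexed by the 3x3 two-locus genotype grid.

    ``offsets[i, j]`` is added to the phenotype when the plant carries
    genotype class ``i`` at ``locus_a`` and ``j`` at ``locus_b``; classes
    are 0 = parent-1 homozygote, 1 = heterozygote, 2 = parent-2 homozygote.
    """

    locus_a: str
    locus_b: str
    offsets: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.offsets, dtype=float)
        if arr.shape != (3, 3) or not np.isfinite(arr).all():
            raise ValueError(
                f"epistatic pair ({self.locus_a}, {self.locus_b}): offsets "
                "must be a finite 3x3 matrix")
        object.__setattr__(self, "offsets", arr)


@dataclass
class QTLArchitecture:
    """The true generative model: trait loci, epistasis, years and noise."""

    loci: list[QTLLocus] = field(default_factory=list)
    epistatic_pairs: list[EpistaticPair] = field(default_factory=list)
    baseline_dth: float = 80.0
    year_effects: dict[int, float] = field(default_factory=lambda: {2015: 0.0})
    noise_sd: float = 2.0

    def __post_init__(self):
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids must be unique")
        known = set(ids)
        for p in self.epistatic_pairs:
            for lid in (p.locus_a, p.locus_b):
                if lid not in known:
                    raise ValueError(f"epistatic pair references unknown locus {lid!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus(self, locus_id: str) -> QTLLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(f"unknown locus {locus_id!r}")


@dataclass
class CrossConfig:
    """Sizes and rates of the crossing / selection / genotyping design."""

    n_f2: int = 248
    n_f3_lines: int = 132
    plants_phenotyped_per_line: int = 6
    plants_genotyped_per_line: int = 3
    n_tail_early: int = 15
    n_tail_late: int = 15
    conditioning_locus: str | None = None
    markers_per_chromosome: int | dict[str, int] | None = None
    missing_call_rate: float = 0.0
    bp_per_cm: float = 300_000.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_f3_lines > self.n_f2:
            raise ValueError(
                f"n_f3_lines ({self.n_f3_lines}) cannot exceed n_f2 ({self.n_f2})")
        if self.n_tail_early + self.n_tail_late > self.n_f3_lines:
            raise ValueError("tail sizes cannot exceed the number of F3 lines")
        if not (0.0 <= self.missing_call_rate < 1.0):
            raise ValueError("missing_call_rate must be in [0, 1)")
        for name in ("n_f2", "n_f3_lines", "plants_phenotyped_per_line",
                     "plants_genotyped_per_line"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# genome layout: markers + trait loci on a shared coordinate system
# ---------------------------------------------------------------------------

@dataclass
class GenomeLayout:
    """Ordered union of marker and trait-locus positions, per chromosome."""

    ids: list[str]
    chrom: np.ndarray
    cm: np.ndarray
    bp: np.ndarray
    is_marker: np.ndarray
    chrom_slices: dict[str, slice]
    chrom_lengths_cm: dict[str, float]

    def __post_init__(self):
        self.index = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def n_positions(self) -> int:
        return len(self.ids)

    @property
    def marker_ids(self) -> list[str]:
        return [pid for pid, m in zip(self.ids, self.is_marker) if m]

    def position(self, pid: str) -> int:
        try:
            return self.index[pid]
        except KeyError:
            raise KeyError(f"unknown position id {pid!r}") from None


def build_layout(marker_map: MarkerMap, architecture: QTLArchitecture) -> GenomeLayout:
    """Merge the marker map and the architecture's loci into one layout.

    Raises if a trait locus falls on a chromosome absent from the map or
    beyond the chromosome's mapped extent.
    """
    rows = [(r.marker, str(r.chrom), float(r.cM), int(r.bp), True)
            for r in marker_map.data.itertuples(index=False)]
    extent: dict[str, float] = {}
    for _, chrom, cm, _, _ in rows:
        extent[chrom] = max(extent.get(chrom, 0.0), cm)
    for locus in architecture.loci:
        chrom = str(locus.chrom)
        if chrom not in extent or locus.cm > extent[chrom]:
            raise ValueError(
                f"locus {locus.locus_id!r} at {locus.cm} cM on chromosome "
                f"{chrom!r} lies outside the marker map range")
        if locus.locus_id in marker_map:
            raise ValueError(
                f"locus id {locus.locus_id!r} collides with a marker id")
        rows.append((locus.locus_id, chrom, float(locus.cm), int(locus.bp), False))
    chrom_order = list(dict.fromkeys(r[1] for r in rows))
    rows.sort(key=lambda r: (chrom_order.index(r[1]), r[2], r[4]))
    ids = [r[0] for r in rows]
    chrom_arr = np.array([r[1] for r in rows], dtype=object)
    cm = np.array([r[2] for r in rows], dtype=float)
    bp = np.array([r[3] for r in rows], dtype=np.int64)
    is_marker = np.array([r[4] for r in rows], dtype=bool)
    slices: dict[str, slice] = {}
    start = 0
    for c in chrom_order:
        n = int((chrom_arr == c).sum())
        slices[c] = slice(start, start + n)
        start += n
    lengths = {c: float(cm[slices[c]].max()) for c in chrom_order}
    return GenomeLayout(ids, chrom_arr, cm, bp, is_marker, slices, lengths)


def random_marker_map(chrom_lengths_cm: Mapping[str, float],
                      n_markers: int | Mapping[str, int],
                      rng: np.random.Generator,
                      bp_per_cm: float = 300_000.0,
                      prefix: str = "M") -> MarkerMap:
    """Scatter markers uniformly along chromosomes (ddRAD-like panel).

    ``n_markers`` is either a total (allocated proportionally to genetic
    length, largest-remainder rounding) or an explicit per-chromosome count.
    Physical bp positions follow the genetic positions through a constant
    ``bp_per_cm`` ratio.
    """
    chroms = list(chrom_lengths_cm)
    if isinstance(n_markers, Mapping):
        counts = {c: int(n_markers.get(c, 0)) for c in chroms}
    else:
        total = int(n_markers)
        lengths = np.array([chrom_lengths_cm[c] for c in chroms], float)
        raw = total * lengths / lengths.sum()
        counts_arr = np.floor(raw).astype(int)
        rem = raw - counts_arr
        for i in np.argsort(-rem)[: total - counts_arr.sum()]:
            counts_arr[i] += 1
        counts = dict(zip(chroms, counts_arr))
    records = []
    for c in chroms:
        k = counts[c]
        if k == 0:
            continue
        pos = np.sort(rng.uniform(0.0, chrom_lengths_cm[c], k))
        bp = np.maximum(1, np.round(pos * bp_per_cm).astype(np.int64))
        bp = np.maximum(bp, np.arange(k) + 1)  # resolve rounding collisions
        for i in range(1, k):
            if bp[i] <= bp[i - 1]:
                bp[i] = bp[i - 1] + 1
        for i, (p, b) in enumerate(zip(pos, bp), start=1):
            records.append((f"{prefix}{c}_{i:04d}", c, int(b), float(p)))
    return MarkerMap(pd.DataFrame(records, columns=["marker", "chrom", "bp", "cM"]))


# ---------------------------------------------------------------------------
# transmission
# ---------------------------------------------------------------------------

def build_parents(architecture: QTLArchitecture, marker_map: MarkerMap
                  ) -> tuple[GenomeLayout, np.ndarray, np.ndarray]:
    """Fully homozygous parental genomes, opposite at every position.

    Returns the merged genome layout together with the two parents as
    ``(2, n_positions)`` haplotype arrays of parental-origin labels.
    """
    layout = build_layout(marker_map, architecture)
    p1 = np.zeros((2, layout.n_positions), dtype=np.int8)
    p2 = np.ones((2, layout.n_positions), dtype=np.int8)
    return layout, p1, p2


def gametes_batch(genomes: np.ndarray, parent_idx: np.ndarray,
                  layout: GenomeLayout, rng: np.random.Generator) -> np.ndarray:
    """Draw one gamete per entry of ``parent_idx`` from ``genomes``.

    ``genomes`` has shape (k, 2, P); ``parent_idx`` (n,) selects the meiotic
    parent of each gamete.  Crossovers per chromosome are Poisson with mean
    map-length/100 (Haldane, no interference), positions uniform in cM.
    """
    genomes = np.asarray(genomes, dtype=np.int8)
    parent_idx = np.asarray(parent_idx)
    n = len(parent_idx)
    out = np.empty((n, layout.n_positions), dtype=np.int8)
    for chrom, sl in layout.chrom_slices.items():
        pos = layout.cm[sl]
        length = layout.chrom_lengths_cm[chrom]
        start = rng.integers(0, 2, size=n)
        k = rng.poisson(length / 100.0, size=n) if length > 0 else np.zeros(n, int)
        kcap = int(k.max()) if n else 0
        if kcap == 0:
            parity = np.broadcast_to(start[:, None], (n, len(pos)))
        else:
            x = rng.uniform(0.0, length, size=(n, kcap))
            live = np.arange(kcap)[None, :] < k[:, None]
            x = np.where(live, x, np.inf)
            crossings = (x[:, :, None] < pos[None, None, :]).sum(axis=1)
            parity = (start[:, None] + crossings) % 2
        seg = genomes[:, :, sl]
        out[:, sl] = seg[parent_idx[:, None], parity,
                         np.arange(len(pos))[None, :]]
    return out


def meiosis(genome: np.ndarray, layout: GenomeLayout,
            rng: np.random.Generator) -> np.ndarray:
    """One gamete haplotype from one diploid genome."""
    return gametes_batch(genome[None, :, :], np.zeros(1, int), layout, rng)[0]


def gametes(genome: np.ndarray, layout: GenomeLayout, n: int,
            rng: np.random.Generator) -> np.ndarray:
    """``n`` independent gametes from one diploid genome."""
    return gametes_batch(genome[None, :, :], np.zeros(n, int), layout, rng)


def self_batch(genomes: np.ndarray, parent_idx: np.ndarray,
               layout: GenomeLayout, rng: np.random.Generator) -> np.ndarray:
    """Self-pollination: one offspring (two gametes) per parent_idx entry."""
    a = gametes_batch(genomes, parent_idx, layout, rng)
    b = gametes_batch(genomes, parent_idx, layout, rng)
    return np.stack([a, b], axis=1)


def genotype_codes(plants: np.ndarray, positions: Sequence[int]) -> np.ndarray:
    """Genotype class (0/1/2 parent-2 allele dosage) at selected positions.

    ``plants`` is (n, 2, P); result is (n, len(positions)) int8.
    """
    idx = np.asarray(positions, dtype=int)
    return (plants[:, 0, idx] + plants[:, 1, idx]).astype(np.int8)


# ---------------------------------------------------------------------------
# phenotype model
# ---------------------------------------------------------------------------

def genetic_values(geno: np.ndarray, architecture: QTLArchitecture,
                   locus_ids: Sequence[str]) -> np.ndarray:
    """Genetic contribution (days) for genotype classes at the given loci."""
    geno = np.asarray(geno)
    value = np.zeros(geno.shape[0])
    col = {lid: j for j, lid in enumerate(locus_ids)}
    for locus in architecture.loci:
        g = geno[:, col[locus.locus_id]]
        if locus.shortening_parent == PARENT1:
            value += locus.additive * (g - 1)
        else:
            value += locus.additive * (1 - g)
        if locus.dominance:
            value += locus.dominance * (g == 1)
    for pair in architecture.epistatic_pairs:
        ga = geno[:, col[pair.locus_a]]
        gb = geno[:, col[pair.locus_b]]
        value += pair.offsets[ga, gb]
    return value


def phenotype_plants(plants: np.ndarray, layout: GenomeLayout,
                     architecture: QTLArchitecture, year: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Plant-level DTH for a batch of diploid genomes in a given year."""
    if year not in architecture.year_effects:
        raise ValueError(
            f"unknown year {year}; architecture defines "
            f"{sorted(architecture.year_effects)}")
    lids = architecture.locus_ids
    pos = [layout.position(l) for l in lids]
    geno = genotype_codes(plants, pos) if lids else np.zeros((len(plants), 0), np.int8)
    dth = (architecture.baseline_dth
           + architecture.year_effects[year]
           + genetic_values(geno, architecture, lids))
    if architecture.noise_sd > 0:
        dth = dth + rng.normal(0.0, architecture.noise_sd, size=len(plants))
    return dth


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

@dataclass
class Line:
    """A selfed line: founder plant plus its selfed progeny plants."""

    line_id: str
    generation: str
    parent: str            # pedigree link: founding ancestor id
    founder: np.ndarray    # (2, P)
    plants: np.ndarray     # (n_plants, 2, P)


@dataclass
class CrossSimulation:
    """All generations of one simulated cross plus selection bookkeeping."""

    architecture: QTLArchitecture
    config: CrossConfig
    layout: GenomeLayout
    f1: np.ndarray
    f2: np.ndarray
    f3_lines: list[Line]
    f3_phenotypes: PhenotypeTable
    f3_line_means: pd.Series
    early_ids: list[str]
    late_ids: list[str]
    f4_lines: list[Line]

    def population_of(self, line_id: str) -> str:
        if line_id in self.early_ids:
            return "early"
        if line_id in self.late_ids:
            return "late"
        return "unselected"


def assign_phenotypes(lines: Sequence[Line], layout: GenomeLayout,
                      architecture: QTLArchitecture, year: int,
                      rng: np.random.Generator,
                      n_plants: int | None = None) -> PhenotypeTable:
    """Phenotype the first ``n_plants`` plants of each line in one year."""
    records = []
    for line in lines:
        plants = line.plants if n_plants is None else line.plants[:n_plants]
        dth = phenotype_plants(plants, layout, architecture, year, rng)
        for j, v in enumerate(dth, start=1):
            records.append((line.line_id, year, j, v))
    return PhenotypeTable(pd.DataFrame(
        records, columns=["line", "year", "plant", "dth"]))


def consensus_call(calls: np.ndarray) -> int:
    """Line-level call from plant-level calls: unanimous or heterozygous.

    A line is called homozygous only if every non-missing plant call agrees;
    any disagreement (a segregating line) is reported as heterozygous.
    """
    obs = calls[calls != CALL_NA]
    if obs.size == 0:
        return CALL_NA
    first = obs[0]
    if (obs == first).all():
        return int(first)
    return CALL_H


def select_tails(line_means: pd.Series,
                 conditioning_calls: pd.Series | None,
                 n_early: int, n_late: int) -> tuple[list[str], list[str]]:
    """Pick the ``n_early`` earliest and ``n_late`` latest eligible lines.

    Lines not homozygous (or missing) at the conditioning locus are excluded
    first; ties in line mean break by line id order.
    """
    means = line_means.sort_index()
    if conditioning_calls is not None:
        hom = conditioning_calls.reindex(means.index).isin([CALL_A, CALL_B])
        means = means[hom.fillna(False)]
    if len(means) < n_early + n_late:
        raise ValueError(
            f"only {len(means)} eligible lines for {n_early}+{n_late} tails")
    order = means.reset_index()
    order.columns = ["line", "mean"]
    order = order.sort_values(["mean", "line"], kind="stable")
    early = order["line"].head(n_early).tolist()
    late = order["line"].tail(n_late).tolist()
    return early, late


def genotype_markers(lines: Sequence[Line], layout: GenomeLayout,
                     missing_call_rate: float, rng: np.random.Generator,
                     populations: Mapping[str, str] | None = None,
                     n_plants: int | None = None,
                     positions: Sequence[str] | None = None) -> GenotypeMatrix:
    """Plant-level genotype calls at marker positions, with random dropout.

    Each (marker, plant) call is independently masked missing with
    probability ``missing_call_rate``, emulating ddRAD coverage gaps.
    Samples are named ``<line_id>:p<i>``.
    """
    if not (0.0 <= missing_call_rate < 1.0):
        raise ValueError("missing_call_rate must be in [0, 1)")
    marker_ids = list(positions) if positions is not None else layout.marker_ids
    idx = [layout.position(m) for m in marker_ids]
    sample_ids: list[str] = []
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for line in lines:
        plants = line.plants if n_plants is None else line.plants[:n_plants]
        geno = genotype_codes(plants, idx)  # (n_plants, n_markers)
        for j in range(len(plants)):
            sample_ids.append(f"{line.line_id}:p{j + 1}")
            cols.append(geno[j])
            labels.append((populations or {}).get(line.line_id, "unselected"))
    calls = (np.stack(cols, axis=1) if cols
             else np.empty((len(marker_ids), 0), np.int8)).astype(np.int8)
    if missing_call_rate > 0 and calls.size:
        mask = rng.random(calls.shape) < missing_call_rate
        calls[mask] = CALL_NA
    return GenotypeMatrix(marker_ids, sample_ids, calls,
                          np.array(labels, dtype=object))


def consensus_genotypes(plant_matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Collapse a plant-level matrix (samples ``line:pN``) to line level."""
    line_of = [s.rsplit(":", 1)[0] for s in plant_matrix.samples]
    lines = list(dict.fromkeys(line_of))
    col_idx = {l: [j for j, s in enumerate(line_of) if s == l] for l in lines}
    calls = np.empty((plant_matrix.n_markers, len(lines)), dtype=np.int8)
    pops = []
    for jl, l in enumerate(lines):
        cols = col_idx[l]
        pops.append(plant_matrix.populations[cols[0]])
        sub = plant_matrix.calls[:, cols]
        for i in range(plant_matrix.n_markers):
            calls[i, jl] = consensus_call(sub[i])
    return GenotypeMatrix(plant_matrix.markers, lines, calls,
                          np.array(pops, dtype=object))


def simulate_pedigree(architecture: QTLArchitecture, config: CrossConfig,
                      marker_map: MarkerMap,
                      selection_year: int | None = None) -> CrossSimulation:
    """Run the full crossing and selection cascade.

    F1 = P1 x P2; ``n_f2`` selfed F2 plants; ``n_f3_lines`` random F2 plants
    each found an F3 line; F3 lines are phenotyped (``selection_year``,
    default the earliest year in the architecture) and the tails selected,
    excluding lines not homozygous at the conditioning locus; one random
    plant of each selected F3 line is selfed to found the F4 line.  With
    both tail sizes zero, every F3 line is advanced to F4 unselected.
    """
    rng = np.random.default_rng(config.rng_seed)
    layout, p1, p2 = build_parents(architecture, marker_map)
    f1 = np.stack([p1[0], p2[0]], axis=0)
    n_plants = max(config.plants_phenotyped_per_line,
                   config.plants_genotyped_per_line)

    f2 = self_batch(f1[None, :, :], np.zeros(config.n_f2, int), layout, rng)
    founders_idx = rng.choice(config.n_f2, size=config.n_f3_lines, replace=False)
    parent_rep = np.repeat(np.arange(config.n_f3_lines), n_plants)
    f3_plants = self_batch(f2[founders_idx], parent_rep, layout, rng)
    f3_lines = []
    for j in range(config.n_f3_lines):
        f3_lines.append(Line(
            line_id=f"L{j + 1:03d}", generation="F3",
            parent=f"F2-{founders_idx[j] + 1}",
            founder=f2[founders_idx[j]],
            plants=f3_plants[j * n_plants:(j + 1) * n_plants]))

    if selection_year is None:
        selection_year = min(architecture.year_effects)
    f3_phen = assign_phenotypes(f3_lines, layout, architecture, selection_year,
                                rng, n_plants=config.plants_phenotyped_per_line)
    line_means = f3_phen.line_means(selection_year)

    conditioning = None
    if config.conditioning_locus is not None:
        pos = layout.position(config.conditioning_locus)
        calls = {}
        for line in f3_lines:
            plant_calls = genotype_codes(
                line.plants[:config.plants_genotyped_per_line], [pos])[:, 0]
            calls[line.line_id] = consensus_call(plant_calls)
        conditioning = pd.Series(calls)

    if config.n_tail_early or config.n_tail_late:
        early, late = select_tails(line_means, conditioning,
                                   config.n_tail_early, config.n_tail_late)
        selected = early + late
    else:
        early, late = [], []
        selected = [l.line_id for l in f3_lines]

    by_id = {l.line_id: l for l in f3_lines}
    sel_lines = [by_id[lid] for lid in selected]
    founder_pick = rng.integers(0, n_plants, size=len(sel_lines))
    founders = np.stack([l.plants[k] for l, k in zip(sel_lines, founder_pick)])
    parent_rep = np.repeat(np.arange(len(sel_lines)), n_plants)
    f4_plants = self_batch(founders, parent_rep, layout, rng)
    f4_lines = []
    for j, line in enumerate(sel_lines):
        f4_lines.append(Line(
            line_id=line.line_id, generation="F4",
            parent=f"{line.line_id}:p{founder_pick[j] + 1}",
            founder=founders[j],
            plants=f4_plants[j * n_plants:(j + 1) * n_plants]))

    return CrossSimulation(
        architecture=architecture, config=config, layout=layout,
        f1=f1, f2=f2, f3_lines=f3_lines, f3_phenotypes=f3_phen,
        f3_line_means=line_means, early_ids=early, late_ids=late,
        f4_lines=f4_lines)
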