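"""Grouping of distortion-flagged markers into physical QTL candidate clusters.

Flagged markers that sit close together on a chromosome usually tag the same
underlying locus.  Markers are chained along each chromosome while the
running physical span of the growing cluster stays within ``max_span``
(3.5 Mb by default); chains smaller than ``min_size`` are reported
separately as unclustered singletons rather than silently discarded.  The
cluster member with the largest marker genotype value represents the
cluster in downstream two-locus analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MarkerMap


@dataclass
class Cluster:
    cluster_id: str
    chrom: str
    start_bp: int
    end_bp: int
    members: list[str]            # marker ids, ordered by bp
    member_bp: list[int]
    representative: str | None = None

    @property
    def span(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)
    unclustered: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "cluster": c.cluster_id, "chrom": c.chrom,
            "start_bp": c.start_bp, "end_bp": c.end_bp,
            "n_members": c.n_members, "representative": c.representative,
            "members": ",".join(c.members),
        } for c in self.clusters])


def cluster_snps(flagged: Iterable[str], marker_map: MarkerMap,
                 max_span: float = 3_500_000, min_size: int = 2) -> ClusterSet:
    """Chain flagged markers into clusters with bounded physical span.

    Markers are sorted by (chromosome, bp); a marker joins the current chain
    while the chain's span after joining stays <= ``max_span``, otherwise it
    starts a new chain.  Chains with fewer than ``min_size`` members are
    returned as unclustered.  The partition is independent of input order.
    """
    flagged = list(flagged)
    missing = [m for m in flagged if m not in marker_map]
    if missing:
        raise KeyError(f"flagged markers missing from map: {missing}")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    recs = sorted(
        ((str(marker_map.record(m)["chrom"]), marker_map.bp(m), m) for m in flagged))
    chains: list[list[tuple[str, int, str]]] = []
    for rec in recs:
        if chains and chains[-1][0][0] == rec[0] \
                and rec[1] - chains[-1][0][1] <= max_span:
            chains[-1].append(rec)
        else:
            chains.append([rec])
    result = ClusterSet()
    n = 0
    for chain in chains:
        if len(chain) >= min_size:
            n += 1
            result.clusters.append(Cluster(
                cluster_id=f"Q{n}", chrom=chain[0][0],
                start_bp=chain[0][1], end_bp=chain[-1][1],
                members=[m for _, _, m in chain],
                member_bp=[b for _, b, _ in chain]))
        else:
            result.unclustered.extend(m for _, _, m in chain)
    return result


def representative_snp(cluster: Cluster, mgvs: pd.DataFrame,
                       year: int | None = None) -> str:
    """Cluster member with the largest absolute MGV; ties break to smaller bp.

    ``mgvs`` is a table as produced by :func:`transseg.stats.mgv_table`
    (columns ``marker``, ``mgv``, ``status`` and optionally ``year``).
    """
    table = mgvs
    if year is not None and "year" in table.columns:
        table = table[table["year"] == year]
    table = table[table["status"] == "ok"].set_index("marker")
    best, best_key = None, None
    for m, bp in zip(cluster.members, cluster.member_bp):
        if m not in table.index:
            continue
        a = float(table.loc[m, "mgv"])
        key = (-a, bp)
        if best_key is None or key < best_key:
            best, best_key = m, key
    if best is None:
        raise ValueError(
            f"cluster {cluster.cluster_id} has no member with a testable MGV")
    return best


def assign_representatives(clusters: ClusterSet, mgvs: pd.DataFrame,
                           year: int | None = None) -> ClusterSet:
    """Fill the representative slot of every cluster in place (and return it)."""
    for c in clusters.clusters:
        c.representative = representative_snp(c, mgvs, year)
    return clusters
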