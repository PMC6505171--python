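"""Cluster flagged SNPs into candidate QTL and estimate their effects.

Flagged markers within 3.5 Mb of each other are chained into physical
clusters (candidate QTL regions).  The marker genotype value
A = |B - C| / 2 — half the gap between the two homozygote class means —
estimates each region's additive effect in days; its sign says which
parent's allele shortens heading.
"""

import transseg as ts

arch, cfg = ts.study_preset(seed=42)
data = ts.simulate_study(arch, cfg)

scan = ts.distortion_scan(data.genotypes)
clusters = ts.cluster_snps(scan.flagged, data.marker_map,
                           max_span=3_500_000, min_size=2)
print(f"{len(scan.flagged)} flagged SNPs -> {len(clusters.clusters)} "
      f"clusters + {len(clusters.unclustered)} singletons")

members = [m for c in clusters.clusters for m in c.members]
mgvs = ts.mgv_table(data.genotypes, data.phenotypes, members, 2015)
ts.assign_representatives(clusters, mgvs, 2015)

print("\nlargest clusters (2015 MGVs of representatives):")
frame = clusters.to_frame().sort_values("n_members", ascending=False).head(6)
rep_mgv = mgvs.set_index("marker")["mgv"]
frame["rep_mgv_days"] = frame["representative"].map(rep_mgv).round(2)
print(frame[["cluster", "chrom", "start_bp", "end_bp", "n_members",
             "representative", "rep_mgv_days"]].to_string(index=False))
print("\n-> clusters on the chromosomes carrying the simulated QTL show "
      "the largest effects; each MGV approximates the locus's additive "
      "effect in days")
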