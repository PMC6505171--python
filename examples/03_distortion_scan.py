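"""Segregation-distortion scan: where tail selection skewed the alleles.

In advanced selfed lines the two parental homozygote classes should be 1:1
at a neutral marker.  Selecting phenotypic tails drags trait-linked markers
away from 1:1 inside each tail; a chi-square test per marker flags them.
"""

import transseg as ts

arch, cfg = ts.study_preset(seed=42)
data = ts.simulate_study(arch, cfg)

scan = ts.distortion_scan(data.genotypes, alpha=0.05,
                          scope="either_population")
print(f"markers tested: {len(scan.table)}")
print(f"flagged at P < 0.05 in either tail: {len(scan.flagged)}")

top = scan.table.nsmallest(5, "p_early")[
    ["marker", "n_A_early", "n_B_early", "p_early"]]
print("\nstrongest early-tail distortions:")
print(top.to_string(index=False))

truth = {l.chrom for l in arch.loci}
mm = data.marker_map.data.set_index("marker")
flagged_chroms = mm.loc[scan.flagged, "chrom"].value_counts()
print("\nflagged markers per chromosome (true QTL on "
      f"{sorted(truth)}):")
print(flagged_chroms.to_string())
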