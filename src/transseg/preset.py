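"""Reproduction preset: the A58 x Kitaake heading-date study design.

Two japonica rice varieties adapted to a high-latitude, short-season region
share most of their short-DTH alleles but differ at one known heading locus
(*Hd1*) and a handful of minor QTL with complementary directions.  The
preset encodes six loci whose additive effects are ordered
chr4 > chr10 > chr6 > chr1 > chr2 > Hd1, with the second parent (Kitaake)
carrying the shortening allele on chromosomes 4, 10, 6 and 2 and the first
parent (A58) on chromosome 1 and at *Hd1*, plus one epistatic pair: the
A58 allele on chromosome 1 combined with the Kitaake allele on chromosome
10 shortens heading by an extra offset, making that combination the
earliest.  Effect sizes are configuration defaults scaled from the observed
MGV ranges, not measured constants.

The crossing design is 248 F2 plants, 132 random F3 lines, and 15 + 15
phenotypic tail lines conditioned on homozygosity at *Hd1*, genotyped at a
ddRAD-like panel of 1402 markers with a 20% per-plant-call dropout so that
the 80% call-rate filter leaves several hundred reliable markers.
"""

from __future__ import annotations

import numpy as np

from .sim import CrossConfig, EpistaticPair, QTLArchitecture, QTLLocus

# framework genetic map lengths (cM) for the 12 rice chromosomes
RICE_CHROM_LENGTHS_CM: dict[str, float] = {
    "1": 181.0, "2": 157.0, "3": 166.0, "4": 130.0, "5": 122.0, "6": 125.0,
    "7": 118.0, "8": 121.0, "9": 93.0, "10": 83.0, "11": 117.0, "12": 109.0,
}

BP_PER_CM = 300_000.0

# epistatic bonus (days) for the A58-homozygote @chr1 x Kitaake-homozygote
# @chr10 combination; reproduces the crossing-lines interaction pattern
EPISTASIS_OFFSET_DAYS = 4.0


def study_architecture(noise_sd: float = 2.0) -> QTLArchitecture:
    """Six-locus architecture with complementary allele directions."""
    def locus(lid, chrom, cm, a, short):
        return QTLLocus(locus_id=lid, chrom=chrom, cm=cm,
                        bp=int(round(cm * BP_PER_CM)), additive=a,
                        dominance=0.0, shortening_parent=short)

    loci = [
        locus("qDTH4", "4", 103.0, 5.0, "P2"),
        locus("qDTH10", "10", 55.0, 3.0, "P2"),
        locus("qDTH6", "6", 83.0, 2.0, "P2"),
        locus("qDTH1", "1", 90.0, 1.8, "P1"),
        locus("qDTH2", "2", 60.0, 1.5, "P2"),
        locus("Hd1", "6", 31.0, 1.25, "P1"),
    ]
    offsets = np.zeros((3, 3))
    offsets[0, 2] = -EPISTASIS_OFFSET_DAYS   # A58 hom @chr1, Kitaake hom @chr10
    pairs = [EpistaticPair("qDTH1", "qDTH10", offsets)]
    return QTLArchitecture(
        loci=loci, epistatic_pairs=pairs, baseline_dth=80.0,
        year_effects={2013: 0.0, 2014: -10.0, 2015: -11.0, 2016: -4.0},
        noise_sd=noise_sd)


def study_cross_config(seed: int = 0) -> CrossConfig:
    """Crossing, selection and genotyping sizes of the study design."""
    return CrossConfig(
        n_f2=248, n_f3_lines=132,
        plants_phenotyped_per_line=6, plants_genotyped_per_line=3,
        n_tail_early=15, n_tail_late=15,
        conditioning_locus="Hd1",
        markers_per_chromosome=1402,     # panel size before call-rate filtering
        missing_call_rate=0.2,
        bp_per_cm=BP_PER_CM,
        rng_seed=seed)


def study_preset(seed: int = 0, noise_sd: float = 2.0
                 ) -> tuple[QTLArchitecture, CrossConfig]:
    """The full study preset: (architecture, cross design)."""
    return study_architecture(noise_sd=noise_sd), study_cross_config(seed=seed)
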