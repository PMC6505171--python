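import numpy as np
import pandas as pd
import pytest

import transseg as ts


@pytest.fixture
def two_locus_arch():
    """Two additive loci on separate chromosomes, opposite directions."""
    return ts.QTLArchitecture(
        loci=[
            ts.QTLLocus("qA", "1", 40.0, 12_000_000, 3.0, 0.0, "P2"),
            ts.QTLLocus("qB", "2", 30.0, 9_000_000, 1.5, 0.0, "P1"),
        ],
        epistatic_pairs=[],
        baseline_dth=80.0,
        year_effects={2014: -10.0, 2015: 0.0},
        noise_sd=2.0,
    )


@pytest.fixture
def small_map():
    rows = [
        ("m1", "1", 3_000_000, 10.0),
        ("m2", "1", 12_000_000, 40.0),
        ("m3", "1", 24_000_000, 80.0),
        ("m4", "2", 3_000_000, 10.0),
        ("m5", "2", 9_000_000, 30.0),
        ("m6", "2", 18_000_000, 60.0),
    ]
    return ts.MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]))


@pytest.fixture
def small_cross(two_locus_arch, small_map):
    """A scaled-down tail-selection cross: 60 F2, 40 F3 lines, 5+5 tails."""
    cfg = ts.CrossConfig(
        n_f2=60, n_f3_lines=40, plants_phenotyped_per_line=4,
        plants_genotyped_per_line=3, n_tail_early=5, n_tail_late=5,
        conditioning_locus=None, missing_call_rate=0.0, rng_seed=11)
    return ts.simulate_pedigree(two_locus_arch, cfg, small_map)


@pytest.fixture
def toy_genotypes():
    """12 markers x 10 lines with an obvious distorted marker (m01)."""
    rng = np.random.default_rng(5)
    markers = [f"m{i:02d}" for i in range(1, 13)]
    samples = [f"L{i:02d}" for i in range(1, 11)]
    calls = rng.choice([0, 1, 2], size=(12, 10), p=[0.4, 0.2, 0.4]).astype(np.int8)
    calls[0] = 0  # every line carries the parent-1 homozygote
    pops = np.array(["early"] * 5 + ["late"] * 5, dtype=object)
    return ts.GenotypeMatrix(markers, samples, calls, pops)


@pytest.fixture
def toy_phenotypes():
    rows = []
    for i in range(1, 11):
        for p in range(1, 4):
            rows.append((f"L{i:02d}", 2015, p, 70.0 + i + 0.1 * p))
    return ts.PhenotypeTable(pd.DataFrame(
        rows, columns=["line", "year", "plant", "dth"]))
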