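"""Genetic correctness of the forward simulator."""

import numpy as np
import pandas as pd
import pytest

import transseg as ts
from transseg.io import CALL_A, CALL_B, CALL_H, CALL_NA
from transseg.sim import (build_parents, consensus_call, gametes,
                          genotype_codes, phenotype_plants, self_batch)

from oracles import haldane_recombinant_fraction


class TestParents:
    def test_parents_fully_homozygous_and_opposite(self, two_locus_arch, small_map):
        layout, p1, p2 = build_parents(two_locus_arch, small_map)
        assert layout.n_positions == 6 + 2
        assert (p1[0] == p1[1]).all() and (p1 == 0).all()
        assert (p2[0] == p2[1]).all() and (p2 == 1).all()

    def test_empty_architecture_gives_baseline_phenotype(self, small_map):
        arch = ts.QTLArchitecture(loci=[], year_effects={2015: 3.0},
                                  noise_sd=0.0, baseline_dth=80.0)
        layout, p1, _ = build_parents(arch, small_map)
        dth = phenotype_plants(p1[None], layout, arch, 2015,
                               np.random.default_rng(0))
        assert dth[0] == pytest.approx(83.0)

    def test_locus_outside_map_range_names_the_locus(self, small_map):
        arch = ts.QTLArchitecture(loci=[
            ts.QTLLocus("qFar", "1", 500.0, 150_000_000, 1.0)])
        with pytest.raises(ValueError, match="qFar"):
            build_parents(arch, small_map)

    def test_locus_on_unmapped_chromosome_rejected(self, small_map):
        arch = ts.QTLArchitecture(loci=[
            ts.QTLLocus("qOff", "7", 10.0, 3_000_000, 1.0)])
        with pytest.raises(ValueError, match="qOff"):
            build_parents(arch, small_map)


class TestMeiosis:
    def test_homozygous_genome_transmits_itself(self, two_locus_arch, small_map):
        layout, p1, _ = build_parents(two_locus_arch, small_map)
        g = gametes(p1, layout, 50, np.random.default_rng(0))
        assert (g == 0).all()

    @pytest.mark.parametrize("d_cm", [5.0, 20.0, 50.0])
    def test_recombinant_fraction_matches_haldane(self, d_cm):
        """Empirical r at distance d matches (1 - exp(-2d/100)) / 2."""
        mm = ts.MarkerMap(pd.DataFrame(
            [("a", "1", 1, 0.0), ("b", "1", 1_000_000, d_cm)],
            columns=["marker", "chrom", "bp", "cM"]))
        arch = ts.QTLArchitecture(loci=[])
        layout, p1, p2 = build_parents(arch, mm)
        f1 = np.stack([p1[0], p2[0]])
        n = 50_000
        g = gametes(f1, layout, n, np.random.default_rng(42))
        r_hat = (g[:, 0] != g[:, 1]).mean()
        r = haldane_recombinant_fraction(d_cm)
        assert abs(r_hat - r) < 3 * np.sqrt(r * (1 - r) / n)

    def test_zero_distance_never_recombines(self):
        mm = ts.MarkerMap(pd.DataFrame(
            [("a", "1", 1, 10.0), ("b", "1", 2, 10.0), ("c", "1", 3, 40.0)],
            columns=["marker", "chrom", "bp", "cM"]))
        arch = ts.QTLArchitecture(loci=[])
        layout, p1, p2 = build_parents(arch, mm)
        f1 = np.stack([p1[0], p2[0]])
        g = gametes(f1, layout, 20_000, np.random.default_rng(3))
        assert (g[:, 0] == g[:, 1]).all()


class TestPedigree:
    def test_f2_segregates_1_2_1(self, two_locus_arch, small_map):
        layout, p1, p2 = build_parents(two_locus_arch, small_map)
        f1 = np.stack([p1[0], p2[0]])
        n = 10_000
        f2 = self_batch(f1[None], np.zeros(n, int), layout,
                        np.random.default_rng(1))
        g = genotype_codes(f2, [layout.position("qA")])[:, 0]
        het = (g == 1).mean()
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / n)
        for hom in (0, 2):
            assert abs((g == hom).mean() - 0.25) < 3 * np.sqrt(0.1875 / n)

    def test_too_many_f3_lines_rejected(self):
        with pytest.raises(ValueError, match="n_f3_lines"):
            ts.CrossConfig(n_f2=10, n_f3_lines=20)

    def test_same_seed_reproduces_pedigree(self, two_locus_arch, small_map):
        cfg = ts.CrossConfig(n_f2=30, n_f3_lines=20, n_tail_early=3,
                             n_tail_late=3, plants_phenotyped_per_line=3,
                             plants_genotyped_per_line=2, rng_seed=9)
        a = ts.simulate_pedigree(two_locus_arch, cfg, small_map)
        b = ts.simulate_pedigree(two_locus_arch, cfg, small_map)
        assert a.early_ids == b.early_ids and a.late_ids == b.late_ids
        assert np.array_equal(a.f2, b.f2)
        pd.testing.assert_frame_equal(a.f3_phenotypes.data, b.f3_phenotypes.data)


class TestPhenotypeModel:
    def test_null_model_is_baseline_plus_year(self, small_map):
        arch = ts.QTLArchitecture(loci=[], baseline_dth=80.0,
                                  year_effects={2014: -10.0}, noise_sd=0.0)
        layout, p1, _ = build_parents(arch, small_map)
        plants = np.repeat(p1[None], 5, axis=0)
        dth = phenotype_plants(plants, layout, arch, 2014,
                               np.random.default_rng(0))
        assert dth == pytest.approx([70.0] * 5)

    def test_homozygote_classes_differ_by_2a(self, small_map):
        arch = ts.QTLArchitecture(
            loci=[ts.QTLLocus("q", "1", 40.0, 12_000_000, 2.0, 0.0, "P2")],
            baseline_dth=80.0, year_effects={2015: 0.0}, noise_sd=0.0)
        layout, p1, p2 = build_parents(arch, small_map)
        dth = phenotype_plants(np.stack([p1, p2]), layout, arch, 2015,
                               np.random.default_rng(0))
        # parent 2 carries the shortening allele
        assert dth[0] - dth[1] == pytest.approx(4.0)

    def test_dominance_moves_heterozygote_only(self, small_map):
        arch = ts.QTLArchitecture(
            loci=[ts.QTLLocus("q", "1", 40.0, 12_000_000, 2.0, 1.0, "P2")],
            baseline_dth=80.0, year_effects={2015: 0.0}, noise_sd=0.0)
        layout, p1, p2 = build_parents(arch, small_map)
        f1 = np.stack([p1[0], p2[0]])
        dth = phenotype_plants(np.stack([p1, f1, p2]), layout, arch, 2015,
                               np.random.default_rng(0))
        assert dth[1] - (dth[0] + dth[2]) / 2 == pytest.approx(1.0)

    def test_epistatic_offset_applies_to_one_cell(self, small_map):
        off = np.zeros((3, 3))
        off[0, 2] = -4.0
        arch = ts.QTLArchitecture(
            loci=[ts.QTLLocus("qA", "1", 40.0, 12_000_000, 0.0),
                  ts.QTLLocus("qB", "2", 30.0, 9_000_000, 0.0)],
            epistatic_pairs=[ts.EpistaticPair("qA", "qB", off)],
            baseline_dth=80.0, year_effects={2015: 0.0}, noise_sd=0.0)
        layout, p1, p2 = build_parents(arch, small_map)
        ia, ib = layout.position("qA"), layout.position("qB")
        plant = p1.copy()
        plant[:, ib] = 1  # parent-2 homozygote at qB, parent-1 at qA
        dth = phenotype_plants(np.stack([p1, plant]), layout, arch, 2015,
                               np.random.default_rng(0))
        assert dth[1] - dth[0] == pytest.approx(-4.0)

    def test_unknown_year_raises(self, two_locus_arch, small_map):
        layout, p1, _ = build_parents(two_locus_arch, small_map)
        with pytest.raises(ValueError, match="1999"):
            phenotype_plants(p1[None], layout, two_locus_arch, 1999,
                             np.random.default_rng(0))

    def test_class_mean_gap_recovers_2a_in_f2(self):
        """Monte-Carlo class means recover 2a per locus within 2 SE."""
        effects = (5.0, 3.0, 2.0, 1.5, 1.8, 1.25)
        arch = ts.QTLArchitecture(
            loci=[ts.QTLLocus(f"q{i}", str(i + 1), 50.0, 15_000_000, a,
                              0.0, "P2") for i, a in enumerate(effects)],
            baseline_dth=80.0, year_effects={2015: 0.0}, noise_sd=2.0)
        gm, pt = ts.f2_mapping_population(arch, 500, seed=123, year=2015)
        means = pt.line_means(2015)
        for i, a in enumerate(effects):
            row = gm.row(f"m_q{i}")
            va = means[[s for s, c in zip(gm.samples, row) if c == CALL_A]]
            vb = means[[s for s, c in zip(gm.samples, row) if c == CALL_B]]
            gap = va.mean() - vb.mean()
            se = np.sqrt(va.var(ddof=1) / len(va) + vb.var(ddof=1) / len(vb))
            # six simultaneous checks: use a multiplicity-adjusted 3 SE band
            assert abs(gap - 2 * a) < 3 * se


class TestSelectionAndGenotyping:
    def test_tails_are_extremes_and_disjoint(self, small_cross):
        assert len(small_cross.early_ids) == 5
        assert len(small_cross.late_ids) == 5
        assert not set(small_cross.early_ids) & set(small_cross.late_ids)
        means = small_cross.f3_line_means
        assert means[small_cross.early_ids].max() <= \
            means[small_cross.late_ids].min()

    def test_conditioning_excludes_heterozygous_lines(self):
        means = pd.Series({"L1": 70.0, "L2": 72.0, "L3": 74.0, "L4": 76.0})
        cond = pd.Series({"L1": CALL_H, "L2": CALL_A, "L3": CALL_B,
                          "L4": CALL_A})
        early, late = ts.select_tails(means, cond, 1, 1)
        assert early == ["L2"] and late == ["L4"]

    def test_all_heterozygous_at_conditioning_locus_errors(self):
        means = pd.Series({"L1": 70.0, "L2": 72.0})
        cond = pd.Series({"L1": CALL_H, "L2": CALL_H})
        with pytest.raises(ValueError, match="eligible"):
            ts.select_tails(means, cond, 1, 1)

    def test_unconditioned_tails_are_pure_phenotype_extremes(self):
        means = pd.Series({f"L{i}": float(i) for i in range(1, 7)})
        early, late = ts.select_tails(means, None, 2, 2)
        assert early == ["L1", "L2"] and late == ["L5", "L6"]

    def test_ties_break_by_line_id(self):
        means = pd.Series({"L3": 70.0, "L1": 70.0, "L2": 70.0, "L4": 80.0})
        early, _ = ts.select_tails(means, None, 2, 1)
        assert early == ["L1", "L2"]

    def test_missing_rate_zero_gives_no_missing(self, small_cross):
        gm = ts.genotype_markers(small_cross.f4_lines, small_cross.layout,
                                 0.0, np.random.default_rng(0), n_plants=3)
        assert (gm.calls != CALL_NA).all()

    def test_missing_fraction_matches_rate(self, small_cross):
        rate = 0.3
        gm = ts.genotype_markers(small_cross.f4_lines, small_cross.layout,
                                 rate, np.random.default_rng(0), n_plants=3)
        n = gm.calls.size
        frac = (gm.calls == CALL_NA).mean()
        assert abs(frac - rate) < 3 * np.sqrt(rate * (1 - rate) / n)

    def test_consensus_rules(self):
        assert consensus_call(np.array([CALL_A, CALL_A, CALL_NA], np.int8)) == CALL_A
        assert consensus_call(np.array([CALL_A, CALL_B, CALL_A], np.int8)) == CALL_H
        assert consensus_call(np.array([CALL_A, CALL_H, CALL_A], np.int8)) == CALL_H
        assert consensus_call(np.array([CALL_NA] * 3, np.int8)) == CALL_NA

    def test_selfing_decays_heterozygosity(self, two_locus_arch, small_map):
        """Unlinked-locus heterozygote frequency halves each generation."""
        cfg = ts.CrossConfig(n_f2=2000, n_f3_lines=2000,
                             plants_phenotyped_per_line=1,
                             plants_genotyped_per_line=1,
                             n_tail_early=0, n_tail_late=0, rng_seed=21)
        cross = ts.simulate_pedigree(two_locus_arch, cfg, small_map)
        pos = cross.layout.position("qA")
        for plants, expected in (
                (cross.f2, 0.5),
                (np.stack([l.plants[0] for l in cross.f3_lines]), 0.25),
                (np.stack([l.plants[0] for l in cross.f4_lines]), 0.125)):
            g = genotype_codes(plants, [pos])[:, 0]
            het = (g == 1).mean()
            n = len(g)
            assert abs(het - expected) < \
                2.576 * np.sqrt(expected * (1 - expected) / n)

    def test_allele_frequency_neutral_without_selection(self, two_locus_arch,
                                                        small_map):
        cfg = ts.CrossConfig(n_f2=3000, n_f3_lines=100,
                             plants_phenotyped_per_line=1,
                             plants_genotyped_per_line=1,
                             n_tail_early=0, n_tail_late=0, rng_seed=13)
        cross = ts.simulate_pedigree(two_locus_arch, cfg, small_map)
        for marker in small_map.data["marker"]:
            pos = cross.layout.position(marker)
            freq = cross.f2[:, :, pos].mean()
            n = 2 * len(cross.f2)
            # six markers checked at once: 99.9% per-marker band keeps the
            # familywise error below 1%
            assert abs(freq - 0.5) < 3.29 * np.sqrt(0.25 / n)

    def test_tail_selection_enriches_shortening_allele_monotonically(self):
        """Early-tail shortening-homozygote frequency grows with effect size."""
        freqs = []
        for a in (0.5, 1.5, 3.0):
            hom_short = 0
            total = 0
            for seed in range(8):
                t = ts.single_qtl_tail_design(a, seed=seed)
                # near markers tag the parent-2 shortening allele
                hom_short += t.loc["near_1", "n_B_early"]
                total += t.loc["near_1", "n_B_early"] + t.loc["near_1", "n_A_early"]
            freqs.append(hom_short / total)
        assert freqs[0] > 0.5
        assert freqs[0] < freqs[1] < freqs[2]
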