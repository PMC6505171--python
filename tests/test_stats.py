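"""Unit and property tests of the core statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import transseg as ts
from transseg.io import CALL_A, CALL_B, CALL_NA
from transseg.stats import MGVRecord

from oracles import pearson_stat


class TestTransgressiveIndex:
    def test_range_equal_to_parental_difference_gives_one(self):
        assert ts.transgressive_index([70.0, 75.0], 70.0, 75.0) == pytest.approx(1.0)

    def test_identical_parental_means_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            ts.transgressive_index([70.0, 75.0], 80.0, 80.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ts.transgressive_index([], 80.0, 81.0)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            vals = rng.normal(78, 4, size=50)
            got = ts.transgressive_index(vals, 81.2, 80.5)
            assert got == pytest.approx((max(vals) - min(vals)) / 0.7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1),
           st.floats(-50, 50), st.floats(0.1, 10))
    def test_location_scale_invariance(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        vals = rng.normal(78, 4, size=20)
        base = ts.transgressive_index(vals, 81.2, 80.5)
        moved = ts.transgressive_index(vals * scale + shift,
                                       81.2 * scale + shift,
                                       80.5 * scale + shift)
        assert moved == pytest.approx(base, rel=1e-9)


class TestChi2Gof:
    def test_perfect_fit_has_zero_statistic(self):
        stat, df, p = ts.chi2_gof((25, 50, 25), (1, 2, 1))
        assert stat == pytest.approx(0.0)
        assert df == 2 and p == pytest.approx(1.0)

    def test_statistic_matches_definition(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            counts = rng.integers(0, 40, size=rng.integers(2, 5))
            if counts.sum() == 0:
                continue
            ratio = rng.integers(1, 4, size=len(counts))
            stat, df, _ = ts.chi2_gof(counts, ratio)
            assert stat == pytest.approx(pearson_stat(counts, ratio))
            assert df == len(counts) - 1

    def test_zero_ratio_weight_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ts.chi2_gof((5, 5), (1, 0))

    def test_arity_mismatch_rejected(self):
        with pytest.raises(ValueError, match="arity"):
            ts.chi2_gof((5, 5, 5), (1, 1))


class TestCallRateFilter:
    def test_no_missing_is_identity(self, toy_genotypes):
        out = ts.call_rate_filter(toy_genotypes, 0.8)
        assert out.equals(toy_genotypes)

    def test_threshold_arithmetic(self):
        # 23/30 calls = 0.767 < 0.8 -> removed; 24/30 = 0.8 -> retained
        calls = np.zeros((2, 30), dtype=np.int8)
        calls[0, :7] = CALL_NA
        calls[1, :6] = CALL_NA
        gm = ts.GenotypeMatrix([f"m{i}" for i in range(2)],
                               [f"s{j}" for j in range(30)], calls)
        out = ts.call_rate_filter(gm, 0.8)
        assert out.markers == ["m1"]

    def test_matches_oracle_recount(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([0, 1, 2], size=(200, 30)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.3] = CALL_NA
        gm = ts.GenotypeMatrix([f"m{i}" for i in range(200)],
                               [f"s{j}" for j in range(30)], calls)
        out = ts.call_rate_filter(gm, 0.8)
        survivors = [f"m{i}" for i in range(200)
                     if (calls[i] != CALL_NA).sum() >= 0.8 * 30]
        assert out.markers == survivors


class TestDistortionScan:
    def test_balanced_marker_unflagged(self):
        calls = np.array([[0] * 8 + [2] * 8], dtype=np.int8)
        gm = ts.GenotypeMatrix(["m"], [f"s{j}" for j in range(16)], calls)
        scan = ts.distortion_scan(gm, scope="pooled")
        row = scan.table.iloc[0]
        assert row["chi2_pooled"] == pytest.approx(0.0)
        assert row["p_pooled"] == pytest.approx(1.0)
        assert not row["flagged"]

    def test_no_homozygotes_is_untestable_not_silent(self):
        calls = np.full((1, 10), 1, dtype=np.int8)
        gm = ts.GenotypeMatrix(["m"], [f"s{j}" for j in range(10)], calls)
        scan = ts.distortion_scan(gm, scope="pooled")
        assert scan.table.iloc[0]["status"] == "untestable"
        assert not scan.table.iloc[0]["flagged"]

    def test_either_scope_flags_single_distorted_tail(self):
        calls = np.array([[0] * 10 + [0] * 5 + [2] * 5], dtype=np.int8)
        pops = np.array(["early"] * 10 + ["late"] * 10, dtype=object)
        gm = ts.GenotypeMatrix(["m"], [f"s{j}" for j in range(20)], calls, pops)
        either = ts.distortion_scan(gm, scope="either_population")
        both = ts.distortion_scan(gm, scope="per_population")
        assert either.flagged == ["m"]    # early tail all one homozygote
        assert both.flagged == []         # late tail is balanced

    def test_bh_column_reported_but_not_used_for_flagging(self, toy_genotypes):
        scan = ts.distortion_scan(toy_genotypes, scope="pooled")
        assert "q_pooled" in scan.table.columns
        flagged = scan.table[scan.table["flagged"]]
        assert (flagged["p_pooled"] < scan.alpha).all()


class TestClassMeansAndMGV:
    def _matrix(self, calls_row, samples):
        calls = np.array([calls_row], dtype=np.int8)
        return ts.GenotypeMatrix(["m"], samples, calls)

    def _phen(self, values, samples, year=2015):
        return ts.PhenotypeTable(pd.DataFrame({
            "line": samples, "year": year, "plant": 1, "dth": values}))

    def test_class_means_simple(self):
        samples = ["a", "b", "c", "d"]
        gm = self._matrix([CALL_A, CALL_A, CALL_B, CALL_B], samples)
        pt = self._phen([80.0, 80.0, 78.0, 78.0], samples)
        cm = ts.genotype_class_means(gm, pt, "m", 2015)
        assert cm.table.loc["A", "mean"] == pytest.approx(80.0)
        assert cm.table.loc["B", "mean"] == pytest.approx(78.0)

    def test_contrast_untestable_with_single_line_class(self):
        samples = ["a", "b"]
        gm = self._matrix([CALL_A, CALL_B], samples)
        pt = self._phen([80.0, 78.0], samples)
        assert ts.genotype_class_means(gm, pt, "m", 2015).status == "untestable"

    def test_heterozygote_near_midpoint_for_additive_locus(self):
        arch = ts.QTLArchitecture(
            loci=[ts.QTLLocus("q", "1", 50.0, 15_000_000, 2.0, 0.0, "P2")],
            year_effects={2015: 0.0}, noise_sd=2.0)
        gm, pt = ts.f2_mapping_population(arch, 3000, seed=4, year=2015)
        cm = ts.genotype_class_means(gm, pt, "m_q", 2015)
        mid = (cm.table.loc["A", "mean"] + cm.table.loc["B", "mean"]) / 2
        # het mean within ~4 SE of the homozygote midpoint
        assert abs(cm.table.loc["H", "mean"] - mid) < 0.35

    def test_mgv_from_printed_class_means(self):
        """B = 81.3, C = 78.8 -> A = 1.25, second parent's allele shortens."""
        samples = ["a", "b"]
        gm = self._matrix([CALL_A, CALL_B], samples)
        pt = self._phen([81.3, 78.8], samples)
        rec = ts.mgv(gm, pt, "m", 2015)
        assert rec.mgv == pytest.approx(1.25)
        assert rec.signed == pytest.approx(1.25)
        assert rec.direction == "P2"

    def test_mgv_equal_classes_has_no_direction(self):
        samples = ["a", "b"]
        gm = self._matrix([CALL_A, CALL_B], samples)
        pt = self._phen([80.0, 80.0], samples)
        rec = ts.mgv(gm, pt, "m", 2015)
        assert rec.mgv == 0.0 and rec.direction is None

    def test_mgv_empty_class_untestable(self):
        samples = ["a", "b"]
        gm = self._matrix([CALL_A, CALL_A], samples)
        pt = self._phen([80.0, 82.0], samples)
        assert not ts.mgv(gm, pt, "m", 2015).is_testable

    def test_mgv_symmetric_under_label_swap(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(20)]
        row = rng.choice([CALL_A, CALL_B], size=20)
        vals = rng.normal(75, 3, size=20)
        gm = self._matrix(row, samples)
        swapped = self._matrix(np.where(row == CALL_A, CALL_B, CALL_A), samples)
        pt = self._phen(vals, samples)
        a = ts.mgv(gm, pt, "m", 2015)
        b = ts.mgv(swapped, pt, "m", 2015)
        assert a.mgv == pytest.approx(b.mgv)
        assert a.signed == pytest.approx(-b.signed)


class TestScoreLines:
    def _mgv_rec(self, marker, signed):
        return MGVRecord(marker, 2015, np.nan, np.nan, 1, 1,
                         abs(signed), signed, "P2" if signed > 0 else "P1", "ok")

    def test_opposite_homozygotes_differ_by_twice_mgv(self):
        samples = ["a", "b"]
        gm = ts.GenotypeMatrix(["m"], samples,
                               np.array([[CALL_A, CALL_B]], np.int8))
        pt = ts.PhenotypeTable(pd.DataFrame({
            "line": samples, "year": 2015, "plant": 1, "dth": [80.0, 76.0]}))
        scores = ts.score_lines(gm, {"m": self._mgv_rec("m", 2.0)}, ["m"],
                                pt, 2015, grand_mean=78.0)
        pred = scores.table.set_index("line")["predicted"]
        assert pred["a"] - pred["b"] == pytest.approx(4.0)

    def test_heterozygous_lines_excluded_and_reported(self):
        samples = ["a", "b", "c"]
        gm = ts.GenotypeMatrix(["m"], samples,
                               np.array([[CALL_A, 1, CALL_B]], np.int8))
        pt = ts.PhenotypeTable(pd.DataFrame({
            "line": samples, "year": 2015, "plant": 1,
            "dth": [80.0, 78.0, 76.0]}))
        scores = ts.score_lines(gm, {"m": self._mgv_rec("m", 2.0)}, ["m"],
                                pt, 2015)
        assert scores.excluded == ["b"]
        assert set(scores.table["line"]) == {"a", "c"}

    def test_true_model_fed_back_gives_perfect_ranking(self):
        """With zero noise the MGV predictions reproduce the observed order."""
        arch = ts.QTLArchitecture(
            loci=[ts.QTLLocus("q1", "1", 50.0, 15_000_000, 3.0, 0.0, "P2"),
                  ts.QTLLocus("q2", "2", 50.0, 15_000_000, 1.0, 0.0, "P1")],
            year_effects={2015: 0.0}, noise_sd=0.0)
        gm, pt = ts.f2_mapping_population(arch, 200, seed=6, year=2015)
        loci = ["m_q1", "m_q2"]
        recs = {m: ts.mgv(gm, pt, m, 2015) for m in loci}
        scores = ts.score_lines(gm, recs, loci, pt, 2015)
        assert scores.spearman_rho == pytest.approx(1.0)
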