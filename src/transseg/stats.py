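"""Core statistics for tail-selection QTL detection.

The analysis rests on counts and class means rather than interval mapping:

* the **transgressive index** — the F2 phenotype range divided by the
  parental mean difference — quantifies how far segregants exceed the
  parental phenotypes;
* a **segregation-distortion scan** tests, marker by marker, whether the two
  parental homozygote classes deviate from the 1:1 ratio expected in
  advanced selfed lines (Pearson chi-square); in phenotype-selected tails a
  skew flags linkage to a trait locus;
* the **marker genotype value** (MGV) A = |B - C| / 2, half the difference
  between the two homozygote class means of the trait, estimates the
  additive effect of the locus tagged by a marker;
* **line scoring** predicts each fully homozygous line's phenotype as the
  grand mean plus the sum of signed MGVs of its alleles.

All statistics operate on line means (never raw plant values) whenever line
structure exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CALL_A, CALL_B, CALL_H, CALL_NA, GenotypeMatrix, PhenotypeTable
from .sim import PARENT1, PARENT2

SCOPES = ("pooled", "per_population", "either_population")


def transgressive_index(f2_dth: Sequence[float], p1_mean: float,
                        p2_mean: float) -> float:
    """F2 phenotype range divided by the absolute parental mean difference.

    Invariant under adding a constant to all inputs and under positive
    rescaling.  Undefined (raises) when the parental means coincide, since
    the ratio diverges.
    """
    values = np.asarray(list(f2_dth), dtype=float)
    if values.size == 0:
        raise ValueError("empty F2 sample")
    diff = abs(float(p1_mean) - float(p2_mean))
    if diff == 0:
        raise ValueError(
            "undefined index: identical parental means (zero denominator)")
    return float((values.max() - values.min()) / diff)


def chi2_gof(counts: Sequence[int], expected_ratio: Sequence[float]
             ) -> tuple[float, int, float]:
    """Pearson goodness-of-fit test of counts against a ratio.

    Expected counts are the ratio scaled to the observed total; the p-value
    is the upper chi-square tail with k - 1 degrees of freedom.
    """
    obs = np.asarray(list(counts), dtype=float)
    ratio = np.asarray(list(expected_ratio), dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError(
            f"counts ({obs.size}) and ratio ({ratio.size}) differ in arity")
    if (obs < 0).any() or not np.all(obs == np.floor(obs)):
        raise ValueError("counts must be non-negative integers")
    if (ratio <= 0).any():
        raise ValueError("ratio weights must all be positive (zero expected cell)")
    total = obs.sum()
    if total == 0:
        raise ValueError("total count must be positive")
    exp = total * ratio / ratio.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    return stat, df, float(sps.chi2.sf(stat, df))


def call_rate_filter(gm: GenotypeMatrix, min_call_rate: float = 0.8
                     ) -> GenotypeMatrix:
    """Retain markers genotyped in at least ``min_call_rate`` of samples."""
    if not (0.0 < min_call_rate <= 1.0):
        raise ValueError("min_call_rate must be in (0, 1]")
    keep = gm.call_rate() >= min_call_rate
    return gm.subset_markers([m for m, k in zip(gm.markers, keep) if k])


@dataclass
class DistortionScan:
    """Per-marker segregation test results plus the flagged-marker set."""

    table: pd.DataFrame
    flagged: list[str]
    alpha: float
    scope: str


def _test_1to1(n_a: int, n_b: int) -> tuple[float, float, str]:
    if n_a + n_b == 0:
        return np.nan, np.nan, "untestable"
    stat, _, p = chi2_gof((n_a, n_b), (1, 1))
    return stat, p, "ok"


def distortion_scan(gm: GenotypeMatrix, alpha: float = 0.05,
                    scope: str = "either_population") -> DistortionScan:
    """Scan every marker for distortion of the homozygote 1:1 ratio.

    Heterozygous and missing calls are excluded.  ``scope`` picks which
    counts drive flagging: ``pooled`` tests all samples together;
    ``either_population`` and ``per_population`` test the early and late
    tails separately — the former flags a marker when either tail is
    distorted at ``alpha``, the latter (the conservative conjunctive
    reading) only when every testable tail is.  All three sets of counts and p-values are
    reported side by side; markers with no homozygous calls in scope carry
    an ``untestable`` status instead of a silent p-value.  A
    Benjamini-Hochberg column is reported for reference but never used for
    flagging.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for marker in gm.markers:
        rec: dict = {"marker": marker}
        pooled = gm.counts(marker)
        rec.update({"n_A": pooled["A"], "n_H": pooled["H"],
                    "n_B": pooled["B"], "n_NA": pooled["NA"]})
        rec["chi2_pooled"], rec["p_pooled"], pooled_status = _test_1to1(
            pooled["A"], pooled["B"])
        for pop in ("early", "late"):
            c = gm.counts(marker, population=pop)
            rec[f"n_A_{pop}"], rec[f"n_B_{pop}"] = c["A"], c["B"]
            rec[f"chi2_{pop}"], rec[f"p_{pop}"], _ = _test_1to1(c["A"], c["B"])
        if scope == "pooled":
            testable = pooled_status == "ok"
            flag = testable and rec["p_pooled"] < alpha
        else:
            tail_ps = [p for p in (rec["p_early"], rec["p_late"])
                       if not np.isnan(p)]
            testable = len(tail_ps) > 0
            if not testable:
                flag = False
            elif scope == "either_population":
                flag = min(tail_ps) < alpha
            else:  # per_population: distorted in every testable tail
                flag = max(tail_ps) < alpha
        rec["status"] = "ok" if testable else "untestable"
        rec["flagged"] = bool(flag)
        rows.append(rec)
    table = pd.DataFrame(rows)
    if len(table):
        for col in ("p_pooled", "p_early", "p_late"):
            q = np.full(len(table), np.nan)
            ok = table[col].notna().to_numpy()
            if ok.any():
                q[ok] = sps.false_discovery_control(table[col].to_numpy()[ok])
            table[col.replace("p_", "q_")] = q
    flagged = table.loc[table["flagged"], "marker"].tolist() if len(table) else []
    return DistortionScan(table=table, flagged=flagged, alpha=alpha, scope=scope)


@dataclass
class ClassMeans:
    """Genotype-class phenotype summary at one marker with homozygote contrast."""

    marker: str
    year: int
    table: pd.DataFrame        # rows A/H/B: n, mean, se
    t_stat: float
    t_df: float
    t_p: float
    status: str                # "ok" or "untestable"


def _class_values(gm: GenotypeMatrix, phen: PhenotypeTable, marker: str,
                  year: int) -> dict[int, np.ndarray]:
    means = phen.line_means(year)
    row = gm.row(marker)
    out = {}
    for code in (CALL_A, CALL_H, CALL_B):
        lines = [s for s, c in zip(gm.samples, row) if c == code and s in means.index]
        out[code] = means.loc[lines].to_numpy(dtype=float)
    return out


def genotype_class_means(gm: GenotypeMatrix, phen: PhenotypeTable,
                         marker: str, year: int) -> ClassMeans:
    """Mean line DTH per genotype class plus a Welch homozygote contrast."""
    values = _class_values(gm, phen, marker, year)
    rows = []
    for code, label in ((CALL_A, "A"), (CALL_H, "H"), (CALL_B, "B")):
        v = values[code]
        rows.append({
            "class": label, "n": len(v),
            "mean": float(v.mean()) if len(v) else np.nan,
            "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
        })
    table = pd.DataFrame(rows).set_index("class")
    a, b = values[CALL_A], values[CALL_B]
    if len(a) >= 2 and len(b) >= 2:
        res = sps.ttest_ind(a, b, equal_var=False)
        df = getattr(res, "df", np.nan)
        return ClassMeans(marker, year, table, float(res.statistic),
                          float(df), float(res.pvalue), "ok")
    return ClassMeans(marker, year, table, np.nan, np.nan, np.nan, "untestable")


@dataclass
class MGVRecord:
    """Marker genotype value: additive-effect estimate at one marker."""

    marker: str
    year: int
    b_mean: float          # mean line DTH, parent-1 (A) homozygotes
    c_mean: float          # mean line DTH, parent-2 (B) homozygotes
    n_b: int
    n_c: int
    mgv: float             # A = |B - C| / 2, days
    signed: float          # (B - C) / 2
    direction: str | None  # parent whose allele shortens DTH, or None
    status: str

    @property
    def is_testable(self) -> bool:
        return self.status == "ok"


def mgv(gm: GenotypeMatrix, phen: PhenotypeTable, marker: str,
        year: int) -> MGVRecord:
    """Marker genotype value A = |B - C| / 2 over line means.

    ``B`` and ``C`` are the mean line-level DTH of the two homozygote
    classes; the direction names the parent whose homozygote heads earlier.
    A record with an empty homozygote class is returned as untestable.
    """
    values = _class_values(gm, phen, marker, year)
    a_vals, b_vals = values[CALL_A], values[CALL_B]
    if len(a_vals) == 0 or len(b_vals) == 0:
        return MGVRecord(marker, year, np.nan, np.nan, len(a_vals),
                         len(b_vals), np.nan, np.nan, None, "untestable")
    b_mean = float(a_vals.mean())
    c_mean = float(b_vals.mean())
    signed = (b_mean - c_mean) / 2.0
    direction = None if signed == 0 else (PARENT2 if signed > 0 else PARENT1)
    return MGVRecord(marker, year, b_mean, c_mean, len(a_vals), len(b_vals),
                     abs(signed), signed, direction, "ok")


def mgv_table(gm: GenotypeMatrix, phen: PhenotypeTable,
              markers: Sequence[str], year: int) -> pd.DataFrame:
    """MGV records for several markers as one table (rows in input order)."""
    recs = [mgv(gm, phen, m, year) for m in markers]
    return pd.DataFrame([{
        "marker": r.marker, "year": r.year, "mean_A_hom": r.b_mean,
        "mean_B_hom": r.c_mean, "n_A_hom": r.n_b, "n_B_hom": r.n_c,
        "mgv": r.mgv, "signed": r.signed, "direction": r.direction,
        "status": r.status,
    } for r in recs])


@dataclass
class LineScores:
    """MGV-weighted phenotype predictions and their rank agreement."""

    table: pd.DataFrame        # line, predicted, observed
    excluded: list[str]        # lines not homozygous at all loci
    spearman_rho: float
    spearman_p: float
    grand_mean: float


def score_lines(gm: GenotypeMatrix, mgv_records: Mapping[str, MGVRecord],
                loci: Sequence[str], phen: PhenotypeTable, year: int,
                grand_mean: float | None = None) -> LineScores:
    """Predict line DTH from its allele composition weighted by MGVs.

    Only lines with consensus homozygous calls at every supplied locus are
    scored: predicted = grand mean + sum over loci of the signed MGV carried
    by the line's allele.  Returns the Spearman rank correlation between
    predicted and observed line means.
    """
    missing = [m for m in loci if m not in mgv_records
               or not mgv_records[m].is_testable]
    if missing:
        raise ValueError(f"no testable MGV for loci: {missing}")
    means = phen.line_means(year)
    rows_idx = [gm.marker_index(m) for m in loci]
    eligible, excluded = [], []
    for j, sample in enumerate(gm.samples):
        calls = gm.calls[rows_idx, j]
        if np.isin(calls, (CALL_A, CALL_B)).all() and sample in means.index:
            eligible.append(j)
        else:
            excluded.append(sample)
    if grand_mean is None:
        grand_mean = float(means.loc[[gm.samples[j] for j in eligible]].mean()) \
            if eligible else float("nan")
    recs = []
    for j in eligible:
        sample = gm.samples[j]
        pred = grand_mean
        for m, i in zip(loci, rows_idx):
            signed = mgv_records[m].signed
            pred += signed if gm.calls[i, j] == CALL_A else -signed
        recs.append({"line": sample, "predicted": pred,
                     "observed": float(means[sample])})
    table = pd.DataFrame(recs, columns=["line", "predicted", "observed"])
    if len(table) >= 3 and table["predicted"].nunique() > 1 \
            and table["observed"].nunique() > 1:
        rho, p = sps.spearmanr(table["predicted"], table["observed"])
    else:
        rho, p = np.nan, np.nan
    return LineScores(table=table, excluded=excluded,
                      spearman_rho=float(rho), spearman_p=float(p),
                      grand_mean=grand_mean)
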