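"""Two-locus interaction analysis on homozygous line classes.

For a pair of loci the four homozygote genotype combinations define a 2x2
grid of cell means of the line-level trait.  The interaction contrast

    delta = (mean[A@1, A@2] - mean[A@1, B@2])
          - (mean[B@1, A@2] - mean[B@1, B@2])

is zero in expectation under a purely additive model; a non-zero delta
means the effect of an allele at one locus depends on the genotype at the
other (epistasis).  Because the eligible line sets are tiny and unbalanced,
significance is assessed by permuting phenotypes across the eligible lines;
a two-way ANOVA is available as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CALL_A, CALL_B, GenotypeMatrix, PhenotypeTable

_CELL_LABELS = (("A", "A"), ("A", "B"), ("B", "A"), ("B", "B"))


@dataclass
class InteractionResult:
    """2x2 homozygote cell means, interaction contrast and its p-value."""

    locus_a: str
    locus_b: str
    year: int
    means: np.ndarray          # (2, 2), rows = locus_a class A/B, cols = locus_b
    counts: np.ndarray         # (2, 2) int
    delta: float
    best_combination: tuple[str, str] | None   # allele pair with minimum mean
    p_perm: float | None
    status: str                # "ok" or "untestable"

    def cell_frame(self) -> pd.DataFrame:
        rows = []
        for (la, lb), m, n in zip(_CELL_LABELS, self.means.ravel(),
                                  self.counts.ravel()):
            rows.append({"allele_1": la, "allele_2": lb, "mean": m, "n": int(n)})
        return pd.DataFrame(rows)


def _eligible(gm: GenotypeMatrix, phen: PhenotypeTable, locus_a: str,
              locus_b: str, year: int) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Line means and 2x2 cell index for lines homozygous at both loci."""
    means = phen.line_means(year)
    ra, rb = gm.row(locus_a), gm.row(locus_b)
    y, cell, lines = [], [], []
    for j, sample in enumerate(gm.samples):
        ca, cb = ra[j], rb[j]
        if ca in (CALL_A, CALL_B) and cb in (CALL_A, CALL_B) \
                and sample in means.index:
            y.append(float(means[sample]))
            cell.append((ca == CALL_B) * 2 + (cb == CALL_B))
            lines.append(sample)
    return np.asarray(y), np.asarray(cell, dtype=int), lines


def _cell_stats(y: np.ndarray, cell: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(cell, minlength=4).reshape(2, 2)
    sums = np.bincount(cell, weights=y, minlength=4).reshape(2, 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def _delta(means: np.ndarray) -> float:
    return float((means[0, 0] - means[0, 1]) - (means[1, 0] - means[1, 1]))


def two_locus_means(gm: GenotypeMatrix, phen: PhenotypeTable, locus_a: str,
                    locus_b: str, year: int) -> InteractionResult:
    """Cell means of line DTH over the four homozygote combinations.

    Lines heterozygous or missing at either locus are excluded.  The result
    is untestable when fewer than two cells are populated; the interaction
    contrast requires all four.
    """
    y, cell, _ = _eligible(gm, phen, locus_a, locus_b, year)
    means, counts = _cell_stats(y, cell)
    non_empty = int((counts > 0).sum())
    if non_empty < 2:
        return InteractionResult(locus_a, locus_b, year, means, counts,
                                 np.nan, None, None, "untestable")
    delta = _delta(means) if (counts > 0).all() else np.nan
    flat = np.where(counts.ravel() > 0, means.ravel(), np.inf)
    best = _CELL_LABELS[int(np.argmin(flat))]
    return InteractionResult(locus_a, locus_b, year, means, counts, delta,
                             best, None, "ok")


def permutation_test(gm: GenotypeMatrix, phen: PhenotypeTable, locus_a: str,
                     locus_b: str, year: int, n_perm: int = 1999,
                     rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for the interaction contrast delta.

    Tests the interaction while respecting the main effects: the additive
    (two-main-effects) model is fitted to the eligible lines and its
    residuals are permuted and added back to the fitted values before delta
    is recomputed (Freedman-Lane).  Permuting raw phenotypes would destroy
    the main effects as well and make the interaction p conservative
    whenever the loci have additive effects.  p = (1 + #{|delta_perm| >=
    |delta_obs|}) / (n_perm + 1), so p is always in [1/(n_perm + 1), 1].
    Degenerate inputs (constant phenotypes) give 1.
    """
    rng = rng or np.random.default_rng()
    y, cell, _ = _eligible(gm, phen, locus_a, locus_b, year)
    means, counts = _cell_stats(y, cell)
    if not (counts > 0).all():
        raise ValueError(
            f"permutation test requires all four cells non-empty; counts "
            f"{counts.ravel().tolist()}")
    if np.ptp(y) == 0:
        return 1.0
    delta_obs = abs(_delta(means))
    # additive fit: intercept + locus_a main effect + locus_b main effect
    design = np.column_stack([np.ones_like(y), cell // 2, cell % 2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    onehot = np.zeros((len(y), 4))
    onehot[np.arange(len(y)), cell] = 1.0
    # contrast weights per cell: (AA - AB) - (BA - BB)
    w = np.array([1.0, -1.0, -1.0, 1.0]) / counts.ravel()
    hits = 0
    for _ in range(n_perm):
        yp = fitted + rng.permutation(resid)
        d = float((yp @ onehot) @ w)
        if abs(d) >= delta_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def interaction_scan(gm: GenotypeMatrix, phen: PhenotypeTable,
                     loci: Sequence[str], year: int, n_perm: int = 0,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, list[InteractionResult]]:
    """Evaluate every unordered pair of loci, ranked by |delta|.

    With ``n_perm`` > 0 a permutation p-value is attached to each testable
    pair.  Untestable pairs are propagated (ranked last) rather than
    dropped.
    """
    if len(loci) < 2:
        raise ValueError("interaction scan needs at least two loci")
    results = []
    for a, b in combinations(loci, 2):
        res = two_locus_means(gm, phen, a, b, year)
        if n_perm > 0 and res.status == "ok" and (res.counts > 0).all():
            res.p_perm = permutation_test(gm, phen, a, b, year, n_perm, rng)
        results.append(res)
    results.sort(key=lambda r: (-(abs(r.delta)) if np.isfinite(r.delta)
                                else np.inf))
    table = pd.DataFrame([{
        "locus_a": r.locus_a, "locus_b": r.locus_b, "delta": r.delta,
        "abs_delta": abs(r.delta) if np.isfinite(r.delta) else np.nan,
        "p_perm": r.p_perm,
        "best_combination": None if r.best_combination is None
        else "/".join(r.best_combination),
        "n_min_cell": int(r.counts.min()), "status": r.status,
    } for r in results])
    return table, results


def interaction_anova(gm: GenotypeMatrix, phen: PhenotypeTable, locus_a: str,
                      locus_b: str, year: int) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA cross-check of the interaction term."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y, cell, lines = _eligible(gm, phen, locus_a, locus_b, year)
    df = pd.DataFrame({
        "dth": y,
        "ga": np.where(cell // 2 == 0, "A", "B"),
        "gb": np.where(cell % 2 == 0, "A", "B"),
    })
    model = smf.ols("dth ~ C(ga) * C(gb)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)
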