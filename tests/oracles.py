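"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the implementation paths they check: the Pearson
statistic is recomputed from its definition, chi-square tail probabilities
come from closed forms (erfc for 1 df, exp(-x/2) for 2 df), exact
goodness-of-fit p-values come from full multinomial enumeration, and the
cluster partition is rebuilt by a direct scan over sorted positions.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def pearson_stat(counts, ratio) -> float:
    counts = np.asarray(counts, float)
    ratio = np.asarray(ratio, float)
    expected = counts.sum() * ratio / ratio.sum()
    return float(((counts - expected) ** 2 / expected).sum())


def chi2_tail_closed_form(x: float, df: int) -> float:
    """Upper chi-square tail from closed forms (df 1 and 2 only)."""
    if df == 1:
        return math.erfc(math.sqrt(x / 2.0))
    if df == 2:
        return math.exp(-x / 2.0)
    raise ValueError("closed forms implemented for df in {1, 2}")


def count_vectors(total: int, k: int):
    """All length-k vectors of non-negative integers summing to total."""
    if k == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for rest in count_vectors(total - head, k - 1):
            yield (head,) + rest


def _log_multinomial_pmf(vec, probs) -> float:
    n = sum(vec)
    out = math.lgamma(n + 1)
    for c, p in zip(vec, probs):
        out += c * math.log(p) - math.lgamma(c + 1)
    return out


def exact_multinomial_p(total: int, ratio) -> dict[tuple, float]:
    """Exact P(X^2 >= observed) for every outcome of a multinomial draw.

    Enumerates all count vectors with the given total under cell
    probabilities proportional to ``ratio`` and accumulates tail mass over
    the Pearson statistic.
    """
    ratio = np.asarray(ratio, float)
    probs = ratio / ratio.sum()
    items = []
    for vec in count_vectors(total, len(ratio)):
        items.append((vec, pearson_stat(vec, ratio),
                      math.exp(_log_multinomial_pmf(vec, probs))))
    items.sort(key=lambda t: -t[1])
    out: dict[tuple, float] = {}
    cum = 0.0
    i = 0
    while i < len(items):
        j = i
        block = 0.0
        while j < len(items) and abs(items[j][1] - items[i][1]) < 1e-9:
            block += items[j][2]
            j += 1
        cum += block
        for t in items[i:j]:
            out[t[0]] = cum
        i = j
    return out


def brute_force_clusters(positions: dict[str, tuple[str, int]],
                         max_span: float, min_size: int
                         ) -> tuple[list[list[str]], list[str]]:
    """Reference grouping: scan sorted markers, break when span exceeded.

    ``positions`` maps marker -> (chrom, bp).  Returns (clusters,
    unclustered) with members ordered by position.
    """
    recs = sorted((c, b, m) for m, (c, b) in positions.items())
    groups: list[list[tuple[str, int, str]]] = []
    for rec in recs:
        if groups and groups[-1][0][0] == rec[0] \
                and rec[1] - groups[-1][0][1] <= max_span:
            groups[-1].append(rec)
        else:
            groups.append([rec])
    clusters, singletons = [], []
    for g in groups:
        names = [m for _, _, m in g]
        if len(g) >= min_size:
            clusters.append(names)
        else:
            singletons.extend(names)
    return clusters, singletons


def haldane_recombinant_fraction(d_cm: float) -> float:
    """Map distance (cM) -> recombinant fraction under no interference."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))
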