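"""Set-level enrichment statistics.

Quintile binning of per-gene effect sizes, 2x2 odds-ratio enrichment with the
small-sample (+0.5 per cell) estimator and Yates continuity-corrected
chi-square p-values (the epitools convention), uniform-resampling permutation
tests for gene-set overlaps, and the one-sample normal-approximation
proportion test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OddsRatioResult",
    "PermutationResult",
    "quintile_bins",
    "term_odds_ratio",
    "overlap_permutation_test",
    "proportion_test",
]


# ---------------------------------------------------------------------------
# quantile binning
# ---------------------------------------------------------------------------


def quintile_bins(values: pd.Series | np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equally populated rank-based bins (0 = lowest), stable on ties.

    Ties are broken by input order (stable sort), so even degenerate
    all-equal input yields equally populated bins (with a warning).
    """
    vals = np.asarray(values, float)
    if vals.size < n_bins:
        raise ValueError(f"need at least {n_bins} values for {n_bins} bins")
    if np.unique(vals).size == 1:
        warnings.warn("all values identical; bins assigned by input order", stacklevel=2)
    order = np.argsort(vals, kind="stable")
    bins = np.empty(vals.size, int)
    # split ranks into n_bins nearly equal contiguous blocks
    edges = np.linspace(0, vals.size, n_bins + 1).round().astype(int)
    for b in range(n_bins):
        bins[order[edges[b] : edges[b + 1]]] = b
    return bins


# ---------------------------------------------------------------------------
# odds-ratio enrichment
# ---------------------------------------------------------------------------


@dataclass
class OddsRatioResult:
    table: np.ndarray  # [[a, b], [c, d]] uncorrected counts
    odds_ratio: float  # small-sample (+0.5) estimate
    log2_odds_ratio: float
    ci95: tuple[float, float]
    p_value: float  # Yates continuity-corrected chi-square
    correction: str = "small_sample+yates"


def term_odds_ratio(term_members: set, bin_members: set, universe: set) -> OddsRatioResult:
    """Enrichment of a term within a bin over the universe.

    2x2 table: a = in term & in bin, b = in term only, c = in bin only,
    d = neither.  The odds ratio uses the small-sample estimator
    (a+0.5)(d+0.5)/((b+0.5)(c+0.5)) with a matching Woolf 95% CI; the
    p-value is the Yates continuity-corrected chi-square.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (term_members <= universe and bin_members <= universe):
        raise ValueError("term and bin members must be subsets of the universe")
    a = len(term_members & bin_members)
    b = len(term_members - bin_members)
    c = len(bin_members - term_members)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], float)
    a5, b5, c5, d5 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a5 * d5) / (b5 * c5)
    se = math.sqrt(1 / a5 + 1 / b5 + 1 / c5 + 1 / d5)
    ci = (orr * math.exp(-1.959963984540054 * se), orr * math.exp(1.959963984540054 * se))
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        p = 1.0
    else:
        num = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
        chi2 = num / (r1 * r2 * c1 * c2)
        p = float(stats.chi2.sf(chi2, df=1))
    return OddsRatioResult(table, float(orr), math.log2(orr), ci, p)


# ---------------------------------------------------------------------------
# permutation overlap test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    observed: dict[str, int]  # overlap size per reference combination
    p_values: dict[str, float]
    n_perm: int
    seed: int
    null_overlaps: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def overlap_permutation_test(
    query_set: set,
    reference_sets: dict[str, set],
    universe: set,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the query set's overlaps with reference sets.

    Observed statistics are the overlap sizes of the query with every
    reference set and every multi-way intersection of references (two-way
    and three-way interfaces).  The null redraws a query of the same size
    uniformly from the universe `n_perm` times; p uses the add-one estimator
    p = (1 + #{null >= observed}) / (n_perm + 1), so p is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not query_set <= universe:
        raise ValueError("query must be a subset of the universe")
    rng = np.random.default_rng(seed)
    universe_arr = np.array(sorted(universe))
    k = len(query_set)

    combos: dict[str, set] = {}
    names = sorted(reference_sets)
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(reference_sets[n] for n in combo))
            combos["&".join(combo)] = inter

    observed = {name: len(query_set & s) for name, s in combos.items()}
    # boolean membership masks over the sorted universe for fast resampling
    index = {g: i for i, g in enumerate(universe_arr)}
    masks = {}
    for name, s in combos.items():
        m = np.zeros(len(universe_arr), bool)
        m[[index[g] for g in s if g in index]] = True
        masks[name] = m
    null = {name: np.empty(n_perm, int) for name in combos}
    for i in range(n_perm):
        draw = rng.choice(len(universe_arr), size=k, replace=False)
        for name, m in masks.items():
            null[name][i] = int(m[draw].sum())
    p_values = {
        name: (1 + int((null[name] >= observed[name]).sum())) / (n_perm + 1) for name in combos
    }
    return PermutationResult(observed, p_values, n_perm, seed, null)


# ---------------------------------------------------------------------------
# proportion test
# ---------------------------------------------------------------------------


def proportion_test(
    k: int, n: int, p0: float, exact: bool = False
) -> tuple[float, float]:
    """One-sample test of k/n against the expected proportion p0.

    Returns (z, two-sided p) with z = (k/n − p0)/sqrt(p0(1−p0)/n); with
    `exact=True` the p-value is the exact two-sided binomial instead (z is
    still reported).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not (0 <= k <= n):
        raise ValueError("k must be in [0, n]")
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    z = (k / n - p0) / math.sqrt(p0 * (1 - p0) / n)
    if exact:
        p = stats.binomtest(k, n, p0).pvalue
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
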