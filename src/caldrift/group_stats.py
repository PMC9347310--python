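"""Group-level inferential statistics on counts and proportions.

The tests used to compare drift rates between sound classes: Pearson χ²
(no continuity correction) and Fisher's exact test on changed/unchanged
2×2 tables, the pooled two-proportion z test, the Wilcoxon rank-sum test
with exact small-sample enumeration, Fisher's r-to-z comparison of two
correlations, and a multi-category bootstrap proportion test (simulating
one group's per-category counts from the other group's rates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "ContingencyTable2x2",
    "CategoryProportions",
    "chi2_2x2",
    "fisher_exact_2x2",
    "two_proportion_z",
    "rank_sum_test",
    "bootstrap_proportion_test",
    "fisher_r_compare",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = group, cols = changed/unchanged."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be nonnegative integers")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class CategoryProportions:
    """Per-category counts of a reference and a test group."""

    labels: tuple
    n_ref: tuple
    k_ref: tuple
    n_test: tuple
    k_test: tuple

    def __post_init__(self) -> None:
        lens = {len(x) for x in (self.labels, self.n_ref, self.k_ref, self.n_test, self.k_test)}
        if len(lens) != 1:
            raise ValueError("all fields must have equal length")
        for k, n in zip(self.k_ref + self.k_test, self.n_ref + self.n_test):
            if not 0 <= k <= n:
                raise ValueError("need 0 <= k <= n in every category/group")


def chi2_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson χ² (df=1, no continuity correction) and upper-tail p."""
    arr = table.array
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin: use fisher_exact_2x2")
    stat, p, _, _ = sp_stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fisher_exact_2x2(
    table: ContingencyTable2x2, confidence_level: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Sample odds ratio (a·d)/(b·c), two-sided exact p, and the
    conditional exact confidence interval.

    A zero cell yields an odds ratio of 0 or inf; the CI comes from the
    conditional (noncentral hypergeometric) method.
    """
    arr = table.array
    _, p = sp_stats.fisher_exact(arr, alternative="two-sided")
    if table.b * table.c == 0:
        odds = math.inf if table.a * table.d > 0 else math.nan
    else:
        odds = (table.a * table.d) / (table.b * table.c)
    ci = sp_stats.contingency.odds_ratio(arr, kind="conditional").confidence_interval(
        confidence_level
    )
    return float(odds), float(p), (float(ci.low), float(ci.high))


def two_proportion_z(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float, float]:
    """Pooled-variance z test for two proportions.

    Returns (z, one-sided p in the direction of the observed difference,
    two-sided p). z = (p̂1 − p̂2)/sqrt(p̂(1 − p̂)(1/n1 + 1/n2)).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1)")
    z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    p_one = float(sp_stats.norm.sf(abs(z)))
    return float(z), p_one, 2 * p_one


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sp_stats.rankdata(pooled, method="average")


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 12
) -> tuple[float, float]:
    """Wilcoxon rank-sum test: rank sum of ``x`` in the pooled midranking
    and a two-sided p value.

    When max(n1, n2) <= ``exact_max_n`` the p value is exact, by full
    enumeration of all C(n1+n2, n1) group assignments of the pooled
    midranks (ties handled naturally); otherwise the normal
    approximation with tie correction is used. Two-sided p is twice the
    smaller tail, capped at 1.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    n1, n2 = a.size, b.size
    ranks = _midranks(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())

    if max(n1, n2) <= exact_max_n:
        sums = np.array(
            [ranks[list(idx)].sum() for idx in combinations(range(n1 + n2), n1)]
        )
        eps = 1e-9
        lo = np.mean(sums <= w + eps)
        hi = np.mean(sums >= w - eps)
        p = min(1.0, 2.0 * min(lo, hi))
        return w, float(p)

    # normal approximation with tie correction
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return w, 1.0
    z = (w - mu) / math.sqrt(var)
    return w, float(2 * sp_stats.norm.sf(abs(z)))


def bootstrap_proportion_test(
    categories: CategoryProportions,
    n_sims: int = 10_000,
    seed: int | np.random.Generator = 0,
    rule: str = "all",
) -> float:
    """Multi-category bootstrap comparison of proportions.

    For each simulation round and category, a test-group count
    k* ~ Binomial(n_test, k_ref/n_ref) is drawn from the reference
    group's rate. Under ``rule="all"`` a round is extreme iff
    k*/n_test >= k_test/n_test in every category (the joint reading of
    "equal to or higher across categories"); ``rule="mean"`` instead
    compares the across-category mean of simulated proportions to the
    observed mean. p = (#extreme)/n_sims.
    """
    if rule not in ("all", "mean"):
        raise ValueError("rule must be 'all' or 'mean'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ref = np.asarray(categories.n_ref, dtype=int)
    if np.any(n_ref == 0):
        raise ValueError("reference group has an empty category")
    p_ref = np.asarray(categories.k_ref, dtype=float) / n_ref
    n_test = np.asarray(categories.n_test, dtype=int)
    p_obs = np.asarray(categories.k_test, dtype=float) / n_test

    sims = rng.binomial(n_test, p_ref, size=(n_sims, len(n_test))) / n_test
    if rule == "all":
        extreme = np.all(sims >= p_obs, axis=1)
    else:
        extreme = sims.mean(axis=1) >= p_obs.mean()
    return float(extreme.mean())


def fisher_r_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent Pearson correlations:
    z = (atanh r1 − atanh r2)/sqrt(1/(n1−3) + 1/(n2−3)), two-sided p."""
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValueError("correlations must be strictly inside (−1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * sp_stats.norm.sf(abs(z)))
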