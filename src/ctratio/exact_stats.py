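"""Exact Mann–Whitney rank-sum test (tie-aware) and Bonferroni adjustment.

The two-sided p-value is computed from the exact permutation distribution of
the rank sum conditional on the observed pooled multiset of values.  Ties
are handled with mid-ranks: the null distribution is built over the observed
(possibly tied) rank multiset, which is the only well-defined notion of an
"exact" test under ties.  The distribution is obtained with the classic
shift (count-generating) dynamic program over doubled mid-ranks (doubling
makes mid-ranks integral), so the cost is O(n1 * n * S) with S the doubled
rank total — comfortably fast at the cohort sizes this pipeline targets
(e.g. 48 vs 66).  Counts are held in float64; with C(114, 48) ~ 3e32 well
inside float range, tail probabilities far below 2.2e-16 remain accurate in
relative terms.

For sample sizes beyond a configurable budget the tie-corrected normal
approximation with continuity correction is used instead and flagged on the
result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ValidationError

#: Exact computation is used while n1 * n2 * (n1 + n2) stays below this.
DEFAULT_EXACT_BUDGET = 5_000_000


@dataclass(frozen=True)
class RankTestResult:
    """Mann–Whitney U for group 1 with its exact (or approximate) p-value."""

    u_statistic: float
    p_raw: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approx"
    p_adjusted: float | None = None
    multiplier: int | None = None

    def adjusted(self, n_variables: int = 406, n_comparisons: int = 4) -> "RankTestResult":
        mult = n_variables * n_comparisons
        return replace(self, multiplier=mult,
                       p_adjusted=bonferroni_adjust(self.p_raw, n_variables,
                                                    n_comparisons))


@lru_cache(maxsize=64)
def _rank_sum_counts(n1: int, doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of subsets of size n1 of ``doubled_ranks`` by subset sum.

    Returns an array c where c[s] is the number of n1-subsets with doubled
    rank sum s.  Only the final layer is cached (~100 kB at n=114).
    """
    total = int(sum(doubled_ranks))
    table = np.zeros((n1 + 1, total + 1))
    table[0, 0] = 1.0
    seen = 0
    for d in doubled_ranks:
        seen += 1
        top = min(n1, seen)
        for k in range(top, 0, -1):
            table[k, d:] += table[k - 1, : total + 1 - d]
    return table[n1]


def exact_mann_whitney(x, y, exact_budget: int = DEFAULT_EXACT_BUDGET) -> RankTestResult:
    """Two-sided Mann–Whitney test of location between samples x and y.

    U counts pairs (x_i, y_j) with x_i > y_j plus half the tied pairs.
    The two-sided p doubles the smaller tail of the exact conditional null
    distribution, capped at 1.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if not np.isfinite(pooled).all():
        raise ValidationError("non-finite value passed to exact_mann_whitney")

    ranks = rankdata(pooled)  # mid-ranks
    doubled = np.rint(2 * ranks).astype(np.int64)
    r1_doubled = int(doubled[:n1].sum())
    u = r1_doubled / 2.0 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    if n1 * n2 * n <= exact_budget:
        counts = _rank_sum_counts(min(n1, n2), tuple(sorted(doubled.tolist())))
        # distribution of the smaller group's doubled rank sum; map r1 over
        # if needed via the reflection R_small = T - R_large.
        if n1 <= n2:
            r_small = r1_doubled
        else:
            r_small = int(doubled.sum()) - r1_doubled
        total = counts.sum()
        lower = counts[: r_small + 1].sum() / total
        upper = counts[r_small:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact"
    else:
        p = _normal_approx_p(u, doubled, n1, n2)
        method = "normal_approx"
    return RankTestResult(u_statistic=u, p_raw=float(p), n1=n1, n2=n2,
                          method=method)


def _normal_approx_p(u: float, doubled: np.ndarray, n1: int, n2: int) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n1 + n2
    _, tie_counts = np.unique(doubled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # fully degenerate: all values tied
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


def bonferroni_adjust(p_raw: float, n_variables: int = 406,
                      n_comparisons: int = 4) -> float:
    """Family-wise adjustment p_raw * n_comparisons * n_variables, uncapped.

    The adjusted value may exceed 1; table formatting renders such values as
    ">1".  Significance uses the strict rule p_raw < 0.05 / multiplier.
    """
    if not (0.0 < p_raw <= 1.0):
        raise ValidationError(f"p_raw must be in (0, 1], got {p_raw!r}")
    if n_variables < 1 or n_comparisons < 1:
        raise ValidationError("multiplier factors must be positive integers")
    return p_raw * n_comparisons * n_variables


def is_significant(p_raw: float, alpha: float = 0.05, n_variables: int = 406,
                   n_comparisons: int = 4) -> bool:
    """Strict Bonferroni significance: p_raw < alpha / (n_comparisons * n_variables)."""
    return p_raw < alpha / (n_comparisons * n_variables)
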