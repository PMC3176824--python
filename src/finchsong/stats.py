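"""Nonparametric group comparisons for per-bird song metrics.

The comparisons used throughout the analysis are:

* Mann-Whitney U (two-sided) for two groups — exact permutation null
  for small samples (combined n <= 12), tie-corrected normal
  approximation otherwise;
* Kruskal-Wallis H (tie-corrected, chi-square p) as the omnibus test
  for three or more groups;
* Games-Howell post-hoc pairwise tests: Welch-type t statistics with
  unpooled variances and Welch-Satterthwaite degrees of freedom,
  referred to the studentized range distribution with q = t * sqrt(2).

The Kruskal-Wallis (rank-based) omnibus is deliberately paired with
the means-based Games-Howell post hoc, matching the analysis
convention this package reproduces, without endorsing the pairing.
Significance stars follow the usual convention: * p < 0.05,
** p < 0.01.  No multiple-testing correction is applied beyond
Games-Howell itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "StatResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "games_howell",
    "significance_stars",
    "EXACT_MW_MAX_N",
]

#: largest combined sample size for which the Mann-Whitney null is enumerated
EXACT_MW_MAX_N = 12


@dataclass
class GroupSample:
    """Named group of per-bird metric values."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.name!r} contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class StatResult:
    """One test outcome: statistic, p-value, labels, and method."""

    statistic: float
    p_value: float
    comparison: str
    method: str
    flag: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _u_statistic(pooled_ranks: np.ndarray, idx_a: tuple[int, ...], n_a: int) -> float:
    rank_sum = pooled_ranks[list(idx_a)].sum()
    return rank_sum - n_a * (n_a + 1) / 2.0


def _exact_mann_whitney_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact p by full enumeration of group assignments.

    Midranks handle ties; the two-sided p-value counts assignments
    whose U is at least as extreme (toward either tail) as observed.
    """
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    nm = n_a * n_b
    u_obs = _u_statistic(ranks, tuple(range(n_a)), n_a)
    crit = min(u_obs, nm - u_obs) + 1e-9   # guard float jitter in midranks
    n_total = n_a + n_b
    hits = 0
    total = 0
    for idx in combinations(range(n_total), n_a):
        u = _u_statistic(ranks, idx, n_a)
        if min(u, nm - u) <= crit:
            hits += 1
        total += 1
    return u_obs, hits / total


def mann_whitney_u(a: GroupSample, b: GroupSample) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact permutation null when the combined sample size is at most
    12; otherwise the tie-corrected normal approximation.  Identical
    values across both groups give p = 1, flagged.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("Mann-Whitney requires n >= 2 per group")
    comparison = f"{a.name} vs {b.name}"
    if np.unique(np.concatenate([a.values, b.values])).size == 1:
        return StatResult(a.n * b.n / 2.0, 1.0, comparison,
                          "mann-whitney-u", flag="all values identical")
    if a.n + b.n <= EXACT_MW_MAX_N:
        u, p = _exact_mann_whitney_p(a.values, b.values)
        return StatResult(float(u), float(min(p, 1.0)), comparison,
                          "mann-whitney-u (exact)")
    res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided",
                           method="asymptotic")
    return StatResult(float(res.statistic), float(res.pvalue), comparison,
                      "mann-whitney-u (normal approx.)")


def kruskal_wallis(groups: list[GroupSample]) -> StatResult:
    """Kruskal-Wallis H with tie correction; chi-square p (df = k - 1)."""
    if len(groups) < 3:
        raise ValueError(
            "Kruskal-Wallis needs >= 3 groups; use mann_whitney_u for two"
        )
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.name!r} has fewer than 2 values")
    comparison = " vs ".join(g.name for g in groups)
    pooled = np.concatenate([g.values for g in groups])
    if np.unique(pooled).size == 1:
        return StatResult(0.0, 1.0, comparison, "kruskal-wallis",
                          flag="all values identical")
    h, p = sps.kruskal(*[g.values for g in groups])
    return StatResult(float(h), float(p), comparison, "kruskal-wallis")


def games_howell(groups: list[GroupSample]) -> list[StatResult]:
    """Games-Howell post-hoc tests for all group pairs.

    Per pair: Welch t with unpooled variances, Welch-Satterthwaite
    degrees of freedom, and p from the studentized range distribution
    with q = t * sqrt(2) and k = total number of groups.  A pair whose
    pooled standard error is zero is flagged (p = 1 if the means are
    equal, else p = 0).
    """
    if len(groups) < 2:
        raise ValueError("Games-Howell needs >= 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.name!r} has fewer than 2 values")
    k = len(groups)
    results: list[StatResult] = []
    for ga, gb in combinations(groups, 2):
        comparison = f"{ga.name} vs {gb.name}"
        va = ga.values.var(ddof=1) / ga.n
        vb = gb.values.var(ddof=1) / gb.n
        se = math.sqrt(va + vb)
        diff = float(ga.values.mean() - gb.values.mean())
        if se == 0.0:
            results.append(
                StatResult(float("inf") if diff else 0.0,
                           0.0 if diff else 1.0,
                           comparison, "games-howell", flag="zero variance")
            )
            continue
        t = diff / se
        df = (va + vb) ** 2 / (
            va**2 / (ga.n - 1) + vb**2 / (gb.n - 1)
        )
        q = abs(t) * math.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, df))
        results.append(StatResult(float(t), min(max(p, 0.0), 1.0),
                                  comparison, "games-howell"))
    return results
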