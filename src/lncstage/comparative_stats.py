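"""Fisher's exact test and the Mann-Whitney U test.

Both tests carry exact small-sample paths: the Fisher p-value is computed by
integer hypergeometric enumeration over all tables with the observed margins
(the two-sided value sums every table whose probability does not exceed the
observed one, with exact integer tie handling), and the Mann-Whitney exact
path enumerates the permutation distribution of the rank-sum statistic with
midrank ties via a dynamic program over doubled ranks. Larger Mann-Whitney
samples use the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu as _scipy_mwu
from scipy.stats import rankdata

#: combined sample size up to which the Mann-Whitney test enumerates exactly
MWU_EXACT_LIMIT = 40

_SIDES = ("two", "greater", "less")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    sidedness: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _check_sided(sided: str) -> None:
    if sided not in _SIDES:
        raise ValueError(f"sided must be one of {_SIDES}")


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_exact(table: ContingencyTable2x2, sided: str = "two") -> TestResult:
    """Exact hypergeometric p-value with the observed margins fixed.

    The table probability for cell ``a = x`` is
    ``C(r1, x) * C(r2, c1 - x) / C(N, c1)``; all support probabilities share
    the denominator, so tables are compared by integer numerators and the
    two-sided sum (all tables no more probable than the observed one) is
    exact. The statistic is the sample odds ratio ``ad / bc``.
    """
    _check_sided(sided)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    numerators = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    denom = comb(n, c1)
    obs = numerators[a]
    if sided == "two":
        num = sum(v for v in numerators.values() if v <= obs)
    elif sided == "greater":
        num = sum(v for x, v in numerators.items() if x >= a)
    else:
        num = sum(v for x, v in numerators.items() if x <= a)
    p = float(Fraction(num, denom))
    p = min(max(p, 5e-324), 1.0)
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    return TestResult(odds, p, "fisher_exact", sided)


def proportion_comparison(
    group1: tuple[int, int], group2: tuple[int, int], sided: str = "two"
) -> tuple[ContingencyTable2x2, TestResult]:
    """Fisher comparison of two (successes, total) proportions."""
    (s1, t1), (s2, t2) = group1, group2
    if s1 > t1 or s2 > t2:
        raise ValueError("successes cannot exceed totals")
    table = ContingencyTable2x2(s1, t1 - s1, s2, t2 - s2)
    return table, fisher_exact(table, sided)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _exact_rank_sum_distribution(scaled_ranks: list[int], n_x: int) -> dict[int, int]:
    """Counts of subsets of size n_x by sum of (doubled) midranks.

    dp[j][s] = number of ways to pick j ranks summing to s; integer-exact.
    """
    max_sum = sum(sorted(scaled_ranks)[-n_x:]) if n_x else 0
    dp: list[dict[int, int]] = [dict() for _ in range(n_x + 1)]
    dp[0][0] = 1
    for r in scaled_ranks:
        for j in range(min(n_x, len(scaled_ranks)) - 1, -1, -1):
            if not dp[j]:
                continue
            nxt = dp[j + 1]
            for s, cnt in dp[j].items():
                ns = s + r
                if ns <= max_sum:
                    nxt[ns] = nxt.get(ns, 0) + cnt
    return dp[n_x]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], sided: str = "two"
) -> TestResult:
    """Mann-Whitney U with midrank ties.

    For combined sizes up to ``MWU_EXACT_LIMIT`` the permutation distribution
    of U is enumerated exactly (two-sided: probability of being at least as
    far from the null mean ``n_x n_y / 2`` as observed); larger samples use
    the tie-corrected normal approximation with continuity correction. The
    statistic is U for the first sample.
    """
    _check_sided(sided)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:n_x].sum()) - n_x * (n_x + 1) / 2.0

    if n_x + n_y <= MWU_EXACT_LIMIT:
        scaled = [int(round(2 * r)) for r in ranks]  # midranks doubled -> integers
        dist = _exact_rank_sum_distribution(scaled, n_x)
        total = comb(n_x + n_y, n_x)
        # U doubled: rank-sum*2 - n_x(n_x+1)
        obs2 = int(round(2 * u_x))
        offset = n_x * (n_x + 1)
        mean2 = n_x * n_y  # doubled U has mean n_x*n_y under the null
        if sided == "greater":
            num = sum(c for s, c in dist.items() if s - offset >= obs2)
        elif sided == "less":
            num = sum(c for s, c in dist.items() if s - offset <= obs2)
        else:
            dev = abs(obs2 - mean2)
            num = sum(c for s, c in dist.items() if abs(s - offset - mean2) >= dev)
        p = float(Fraction(num, total))
        p = min(max(p, 5e-324), 1.0)
        return TestResult(u_x, p, "mann_whitney_u_exact", sided)

    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    res = _scipy_mwu(x, y, alternative=alternative, method="asymptotic")
    p = min(max(float(res.pvalue), 5e-324), 1.0)
    return TestResult(float(res.statistic), p, "mann_whitney_u_normal", sided)


# ---------------------------------------------------------------------------
# optional multiple-testing adjustment (off by default in the pipeline)
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[idx] * m / i)
        adjusted[idx] = running
    return np.minimum(adjusted, 1.0)
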