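"""Exact inference primitives: Fisher's exact test and binomial tail sums.

Both tests are computed from first principles. The Fisher test evaluates the
hypergeometric likelihood of every 2x2 table compatible with the observed
margins, in log-space (``math.lgamma``) by default and in exact rational
arithmetic (``fractions.Fraction`` over ``math.comb``) on request for totals
up to a few thousand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b / c, d); rows are the outcome, columns the exposure.

    Conventions used in this package: rows = oxidized yes/no (or reactivity
    low/high), columns = S-aromatic motif yes/no.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("yes", "no")
    col_labels: tuple[str, str] = ("motif", "no-motif")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("counts must be non-negative integers")
        if self.total == 0:
            raise ValueError("all-zero contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        """Sample odds ratio a*d / (b*c); inf/nan on zero cells."""
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class TestResult:
    p_one_sided: float
    p_two_sided: float
    direction: str  # "enrichment" | "depletion" | "none"
    statistic: str
    odds_ratio: float = math.nan


def _log_hypergeom_pmf(k: int, r1: int, r2: int, c1: int) -> float:
    """log P(first cell = k) under fixed margins (r1, r2 rows; c1 first column)."""
    n = r1 + r2

    def lchoose(a: int, b: int) -> float:
        if b < 0 or b > a:
            return -math.inf
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    return lchoose(r1, k) + lchoose(r2, c1 - k) - lchoose(n, c1)


def _hypergeom_pmf_exact(k: int, r1: int, r2: int, c1: int) -> Fraction:
    n = r1 + r2
    if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
        return Fraction(0)
    return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))


def fisher_exact(table: ContingencyTable2x2, exact: bool = False) -> TestResult:
    """Fisher's exact test for a 2x2 table.

    One-sided p is the hypergeometric tail in the observed direction
    (enrichment of the first cell over its expectation, or depletion).
    Two-sided p follows the minimum-likelihood convention: the sum of the
    probabilities of all tables no more likely than the observed one.

    With ``exact=True`` every probability is a rational number and the
    returned p-values are exact to float rounding (practical for totals up to
    a few thousand).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = table.total

    if min(r1, r2, c1, b + d) == 0:
        # a degenerate margin admits a single table: p = 1 identically
        return TestResult(
            p_one_sided=1.0,
            p_two_sided=1.0,
            direction="none",
            statistic="hypergeometric tail (degenerate margin)",
            odds_ratio=table.odds_ratio,
        )

    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    expected_a = r1 * c1 / n
    direction = "enrichment" if a >= expected_a else "depletion"

    if exact:
        pmf = {k: _hypergeom_pmf_exact(k, r1, r2, c1) for k in range(k_min, k_max + 1)}
        p_obs = pmf[a]
        if direction == "enrichment":
            one = sum(pmf[k] for k in range(a, k_max + 1))
        else:
            one = sum(pmf[k] for k in range(k_min, a + 1))
        two = sum(p for p in pmf.values() if p <= p_obs)
        return TestResult(
            p_one_sided=float(one),
            p_two_sided=float(min(two, Fraction(1))),
            direction=direction,
            statistic="hypergeometric tail, exact rational arithmetic",
            odds_ratio=table.odds_ratio,
        )

    logs = {k: _log_hypergeom_pmf(k, r1, r2, c1) for k in range(k_min, k_max + 1)}
    log_obs = logs[a]
    if direction == "enrichment":
        tail = [logs[k] for k in range(a, k_max + 1)]
    else:
        tail = [logs[k] for k in range(k_min, a + 1)]
    one = _logsumexp_sum(tail)
    # tables no more likely than the observed one; tolerance absorbs lgamma
    # rounding so ties in probability are kept (scipy uses the same guard)
    two = _logsumexp_sum([lp for lp in logs.values() if lp <= log_obs + 1e-7])
    return TestResult(
        p_one_sided=min(one, 1.0),
        p_two_sided=min(two, 1.0),
        direction=direction,
        statistic="hypergeometric tail, log-space",
        odds_ratio=table.odds_ratio,
    )


def _logsumexp_sum(logs: list[float]) -> float:
    m = max(logs)
    if m == -math.inf:
        return 0.0
    return math.exp(m) * sum(math.exp(lp - m) for lp in logs)


def binomial_tail(k: int, n: int, p: float = 0.5) -> float:
    """Exact upper tail P[X >= k] for X ~ Binomial(n, p).

    Rational arithmetic when ``p`` is exactly representable (e.g. 0.5), so
    the result is exact to float rounding.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    pf = Fraction(p)
    total = sum(
        Fraction(math.comb(n, x)) * pf**x * (1 - pf) ** (n - x) for x in range(k, n + 1)
    )
    return float(total)


def binomial_point_mass(k: int, n: int, p: float = 0.5) -> float:
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    pf = Fraction(p)
    return float(Fraction(math.comb(n, k)) * pf**k * (1 - pf) ** (n - k))
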