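"""Exact 2x2 contingency inference by hypergeometric enumeration.

Used for the phosphomimetic loop-out viability analysis: rows are the two
constructs compared (e.g. the AA allele vs a DD/EE phosphomimetic), columns
are clone outcomes (retained the mutation vs reverted to wild type).  The
p-values are computed from exact integer combinatorics — every admissible
table at the observed margins is enumerated and its probability accumulated
as a rational number — so the result carries no floating-point accumulation
error.  For very large tables (N > 10,000) a log-space evaluation via
``lgamma`` is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, exp, lgamma

import numpy as np

_EXACT_N_LIMIT = 10_000
# minimum-likelihood two-sided rule: include tables with pmf <= observed,
# up to this relative slack
_TWO_SIDED_SLACK = Fraction(1, 10**7)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table [[a, b], [c, d]]; rows = constructs, columns = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError("table entries must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one nonzero margin")

    @property
    def n(self) -> int:  # first-row total (number drawn)
        return self.a + self.b

    @property
    def K(self) -> int:  # first-column total (successes in population)
        return self.a + self.c

    @property
    def N(self) -> int:  # grand total
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)


def _support(K: int, n: int, N: int) -> range:
    return range(max(0, n - (N - K)), min(n, K) + 1)


def _check_margins(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins: K={K}, n={n}, N={N}")
    if not (max(0, n - (N - K)) <= k <= min(n, K)):
        raise ValueError(f"k={k} outside hypergeometric support for (K={K}, n={n}, N={N})")


def hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n), exact combinatorics.

    C(K,k)*C(N-K,n-k)/C(N,n) evaluated with integer arithmetic (log-space
    above N = 10,000 to avoid gigantic integers).
    """
    _check_margins(k, K, n, N)
    if N <= _EXACT_N_LIMIT:
        return float(Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n)))
    log_p = (
        _lchoose(K, k) + _lchoose(N - K, n - k) - _lchoose(N, n)
    )
    return exp(log_p)


def _lchoose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_exact(
    table: ContingencyTable, alternative: str = "greater"
) -> float:
    """Fisher's exact test p-value for a 2x2 table.

    ``greater``/``less`` are one-sided tail sums over the hypergeometric
    support of the a-cell at fixed margins; ``two_sided`` uses the
    minimum-likelihood rule (sum over tables whose point probability does not
    exceed the observed one, with a tiny relative slack for ties).
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    K, n, N = table.K, table.n, table.N
    support = _support(K, n, N)

    if N <= _EXACT_N_LIMIT:
        denom = comb(N, n)
        nums = {j: comb(K, j) * comb(N - K, n - j) for j in support}
        obs = nums[table.a]
        if alternative == "greater":
            total = sum(v for j, v in nums.items() if j >= table.a)
        elif alternative == "less":
            total = sum(v for j, v in nums.items() if j <= table.a)
        else:
            cutoff = obs + obs * _TWO_SIDED_SLACK
            total = sum(v for v in nums.values() if v <= cutoff)
        p = float(Fraction(total, denom))
    else:
        logs = {j: _lchoose(K, j) + _lchoose(N - K, n - j) - _lchoose(N, n) for j in support}
        obs = logs[table.a]
        if alternative == "greater":
            sel = [v for j, v in logs.items() if j >= table.a]
        elif alternative == "less":
            sel = [v for j, v in logs.items() if j <= table.a]
        else:
            sel = [v for v in logs.values() if v <= obs + 1e-7]
        m = max(sel)
        p = float(exp(m) * sum(exp(v - m) for v in sel))
    return min(p, 1.0)
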