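"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy and the package's own code paths: Fisher
probabilities come from exact rational hypergeometric enumeration, and the
rank-sum null from exhaustive combination enumeration.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by enumerating all tables with fixed margins.

    Tables whose exact hypergeometric probability is at most the observed
    one (with the conventional 1 + 1e-7 relative tie tolerance) contribute.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = pmf(a)
    cutoff = obs * Fraction(10_000_001, 10_000_000)
    total = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= cutoff)
    return float(min(total, Fraction(1)))


def ranksum_two_sided(x: list[float], y: list[float]) -> float:
    """Two-sided rank-sum P by exhaustive enumeration (no ties expected).

    Enumerates every assignment of ranks to the first group and counts
    assignments whose rank-sum is at least as extreme (two-tailed, by
    distance from the null mean) as observed.
    """
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n1, n2 = len(x), len(y)
    mean = n1 * (n1 + n2 + 1) / 2
    dev = abs(w_obs - mean)
    total = extreme = 0
    for subset in combinations(range(1, n1 + n2 + 1), n1):
        total += 1
        if abs(sum(subset) - mean) >= dev - 1e-9:
            extreme += 1
    return extreme / total
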