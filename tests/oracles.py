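"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and where practical the libraries)
they are used to check: the Fisher oracle enumerates the hypergeometric
support with exact integer binomials, the BH oracle applies the step-up
formula literally, and the rank-sum oracle enumerates rank splits.
"""

import itertools
import math
from fractions import Fraction


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by minimum-likelihood enumeration.

    Conditions on the margins and sums the probability of every table whose
    hypergeometric probability does not exceed the observed one (standard
    relative tolerance 1e-7 for ties at the boundary).
    """
    n = a + b + c + d
    row = a + b
    col = a + c
    denom = math.comb(n, col)
    kmin = max(0, row + col - n)
    kmax = min(row, col)
    pmf = {
        k: math.comb(row, k) * math.comb(n - row, col - k) / denom
        for k in range(kmin, kmax + 1)
    }
    p_obs = pmf[a]
    total = sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))
    return min(total, 1.0)


def bh_oracle(p_values):
    """Benjamini-Hochberg step-up by the textbook formula, in input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [None] * m
    running_min = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end  # 1-based ascending rank of p_values[i]
        running_min = min(running_min, m * p_values[i] / rank)
        q[i] = min(running_min, 1.0)
    return q


def rank_sum_exact_oracle(x, y):
    """Two-sided rank-sum p by enumerating all assignments of ranks to group x.

    Assumes no ties. The statistic is the rank sum of x; the p-value is the
    probability of a rank sum at least as extreme (two-sided, by summing
    both tails symmetrically).
    """
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    n, m = len(x), len(y)
    w_obs = sum(ranks[v] for v in x)
    mean_w = n * (n + m + 1) / 2
    dev = abs(w_obs - mean_w)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        total += 1
        if abs(sum(combo) - mean_w) >= dev - 1e-12:
            count += 1
    return count / total


def hypergeom_pmf_fraction(k, n, row, col):
    """Exact rational hypergeometric pmf (used for spot checks)."""
    return Fraction(math.comb(row, k) * math.comb(n - row, col - k), math.comb(n, col))
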