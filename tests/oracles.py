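"""Independent brute-force oracles used by the tests.

These deliberately avoid the library code paths they check: homozygote
counting by explicit genotype enumeration, and Fisher-exact quantities by
full enumeration of the conditional hypergeometric support.
"""

from __future__ import annotations

import math

import numpy as np


def enumerate_homozygotes(hap_a: np.ndarray, hap_b: np.ndarray) -> list[int]:
    """Observed hom-alt count per variant by explicit per-individual loops."""
    n, m = hap_a.shape
    out = []
    for j in range(m):
        count = 0
        for i in range(n):
            if hap_a[i, j] == 1 and hap_b[i, j] == 1:
                count += 1
        out.append(count)
    return out


def enumerate_expected(hap_a: np.ndarray, hap_b: np.ndarray) -> list[float]:
    """Expected hom count n * p**2 with p counted haplotype by haplotype."""
    n, m = hap_a.shape
    out = []
    for j in range(m):
        alt = 0
        for i in range(n):
            alt += int(hap_a[i, j]) + int(hap_b[i, j])
        p = alt / (2 * n)
        out.append(n * p * p)
    return out


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_support(r1: int, c1: int, n: int) -> range:
    """Support of the (2,2)-table cell a given margins (r1, c1, n)."""
    return range(max(0, r1 + c1 - n), min(r1, c1) + 1)


def table_log_prob(a: int, r1: int, c1: int, n: int, psi: float = 1.0) -> float:
    """Unnormalized noncentral hypergeometric log-probability of cell a."""
    return (_log_binom(r1, a) + _log_binom(n - r1, c1 - a)
            + (a * math.log(psi) if psi != 1.0 else 0.0))


def fisher_p_brute(table) -> float:
    """Two-sided Fisher p by full enumeration of the conditional support."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    support = list(hypergeom_support(r1, c1, n))
    logs = np.array([table_log_prob(x, r1, c1, n) for x in support])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[support.index(a)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def conditional_mean(psi: float, r1: int, c1: int, n: int) -> float:
    """E_psi[a | margins] under the noncentral hypergeometric at odds psi."""
    support = list(hypergeom_support(r1, c1, n))
    logs = np.array([table_log_prob(x, r1, c1, n, psi) for x in support])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    return float(np.dot(support, probs))


def cmle_odds_ratio_brute(table, tol: float = 1e-12) -> float:
    """Conditional-MLE odds ratio by bisection on the score equation."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    support = hypergeom_support(r1, c1, n)
    if a == min(support):
        return 0.0
    if a == max(support):
        return math.inf
    lo, hi = 1e-12, 1e12
    while hi / lo > 1 + tol:
        mid = math.sqrt(lo * hi)
        if conditional_mean(mid, r1, c1, n) < a:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)
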