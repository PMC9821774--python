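"""Independent exact-arithmetic oracles used to validate the fast paths.

These enumerate the relevant discrete distributions with rational
arithmetic (fractions.Fraction) and stay deliberately separate from the
implementations they check.
"""

from fractions import Fraction
from math import comb


def binomial_split_pvalue(sa: int, t: int, na: int, nb: int) -> Fraction:
    """Exact two-sided minimum-likelihood p-value for the binomial split.

    Under the Poisson (dispersion 0) null, the group-A sum given total t
    is Binomial(t, na/(na+nb)); the p-value sums all split probabilities
    not exceeding the observed one (exact rational comparison).
    """
    p = Fraction(na, na + nb)
    probs = [comb(t, s) * p**s * (1 - p) ** (t - s) for s in range(t + 1)]
    observed = probs[sa]
    return sum(q for q in probs if q <= observed)


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    total = comb(N, n)
    upper = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return Fraction(upper, total)


def spearman_null_tail(n: int, threshold: float) -> Fraction:
    """P(S < -threshold or S > threshold) for Spearman's S under the exact
    permutation null with n distinct observations (enumeration of n!)."""
    from itertools import permutations

    base = list(range(1, n + 1))
    denom = Fraction(n * (n * n - 1), 6)
    count = 0
    total = 0
    for perm in permutations(base):
        d2 = sum((a - b) ** 2 for a, b in zip(base, perm))
        s = 1 - Fraction(d2) / denom
        if s < -threshold or s > threshold:
            count += 1
        total += 1
    return Fraction(count, total)
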