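"""Independent brute-force oracles used by multiple test modules.

These deliberately take different computational routes than the package
(exact rational arithmetic, full enumeration) so agreement is evidence,
not tautology.
"""

import itertools
from fractions import Fraction
from math import comb, factorial


def hwe_oracle(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Direct-formula exact HWE P with exact rational arithmetic."""
    n = n_het + n_hom_minor + n_hom_major
    rare = 2 * min(n_hom_minor, n_hom_major) + n_het
    if n == 0 or rare == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        ways = (
            Fraction(factorial(n), factorial(hom_r) * factorial(h) * factorial(hom_c))
            * 2**h
        )
        return ways / comb(2 * n, rare)

    configs = [
        h for h in range(rare % 2, rare + 1, 2) if n - h - (rare - h) // 2 >= 0
    ]
    probs = {h: prob(h) for h in configs}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


def mw_exact_oracle(x, y) -> float:
    """Two-sided exact Mann-Whitney P by full enumeration (no ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    m = n1 * len(y)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for ix in itertools.combinations(range(len(pooled)), n1):
        idx = set(ix)
        sel = [pooled[i] for i in ix]
        rest = [v for i, v in enumerate(pooled) if i not in idx]
        us.append(sum(1 for a in sel for b in rest if a > b))
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    return sum(1 for u in us if u <= lo or u >= hi) / len(us)
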