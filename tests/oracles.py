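"""Brute-force reference computations used only to check the package.

These deliberately avoid scipy and the package's own code paths: exact
binomial coefficients via math.comb, plain sums over all outcomes.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_upper_tail_exact(k: int, M: int, w: int, G: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(G, w, M) by direct enumeration."""
    total = comb(G, M)
    acc = Fraction(0)
    for i in range(k, min(M, w) + 1):
        if M - i > G - w:
            continue
        acc += Fraction(comb(w, i) * comb(G - w, M - i), total)
    return acc


def fisher_two_sided_exact(a: int, b: int, c: int, d: int,
                           rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher p by enumerating all tables with the observed
    margins (point-probability convention, with a relative tolerance for
    floating-point ties)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for i in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_i = comb(r1, i) * comb(r2, c1 - i) / denom
        if p_i <= p_obs * (1 + rel_tol):
            total += p_i
    return min(1.0, total)
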