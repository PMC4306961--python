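"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the code paths they verify: the recovery
probability is recomputed by enumerating every multinomial outcome via
scipy's multinomial pmf, and the single-allele case via scipy's closed-form
binomial tail.
"""

from __future__ import annotations

from itertools import product
from typing import Sequence

import numpy as np
from scipy import stats


def enumerate_recovery_probability(n: int, q: Sequence[float], k: int) -> float:
    """P(every allele count >= k) by full enumeration of outcomes.

    Categories are the m alleles plus one error category; every count
    vector summing to n is visited.  Exponential in m, fine for n <= ~20.
    """
    q = np.asarray(list(q) + [1.0 - float(np.sum(q))])
    m = len(q) - 1
    grid = [counts for counts in product(range(n + 1), repeat=m)
            if sum(counts) <= n and all(c >= k for c in counts)]
    if not grid:
        return 0.0
    x = np.array([list(c) + [n - sum(c)] for c in grid])
    return float(stats.multinomial.pmf(x, n, q).sum())


def binomial_tail(n: int, p: float, k: int) -> float:
    """Closed-form P(X >= k), X ~ Binomial(n, p)."""
    return float(stats.binom.sf(k - 1, n, p))
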