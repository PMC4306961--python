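"""Allele-recovery probability and minimum-coverage planning.

When an amplicon from one sample is sequenced to total depth ``n``, each read
is either a correct copy of one of the ``m`` true alleles or an error
(substitution, homopolymer indel, chimera, ...).  With a per-read correct
probability ``p`` and amplification weights ``w_1..w_m`` over the alleles,
read categories follow a multinomial with per-allele probabilities
``q_i = p * w_i / sum(w)`` and an error category ``1 - p``.

A genotype is considered safely recoverable once every true allele is
represented by at least ``k`` identical correct reads (default 3).  This
module computes the probability of that event exactly, by inclusion–exclusion
over the shortfall events "allele i has fewer than k copies", and inverts it
to find the smallest coverage ``n`` reaching a stated confidence (default
99.9%).  A seeded Monte-Carlo estimator serves as an independent check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln, xlogy

__all__ = [
    "AlleleProfile",
    "RecoveryTarget",
    "CoverageResult",
    "MonteCarloEstimate",
    "PInterval",
    "recovery_probability",
    "min_coverage",
    "mc_recovery",
    "consistent_p_interval",
]

_MAX_COVERAGE_SEARCH = 100_000_000


@dataclass(frozen=True)
class AlleleProfile:
    """Per-read outcome model for one locus in one sample.

    Parameters
    ----------
    p_correct
        Probability that a read is an exact copy of *some* true allele
        (the observed proportion of correct reads for an enzyme).
    weights
        Relative amplification weights of the ``m`` alleles.  ``(1,)`` for a
        haplotype, ``(1, 1)`` for two alleles amplifying equally, ``(2, 1)``
        when one allele amplifies half as well as the other.  Correct reads
        split between alleles in proportion to the weights:
        ``q_i = p_correct * w_i / sum(w)``.
    """

    p_correct: float
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError(f"p_correct must be in [0, 1], got {self.p_correct}")
        w = tuple(float(x) for x in self.weights)
        if len(w) < 1:
            raise ValueError("at least one allele weight is required")
        if any(x <= 0 or not math.isfinite(x) for x in w):
            raise ValueError(f"allele weights must be positive and finite, got {w}")
        object.__setattr__(self, "weights", w)

    @property
    def m(self) -> int:
        """Number of alleles."""
        return len(self.weights)

    @property
    def q(self) -> np.ndarray:
        """Per-read probabilities of being a correct copy of each allele."""
        w = np.asarray(self.weights, dtype=float)
        return self.p_correct * w / w.sum()


@dataclass(frozen=True)
class RecoveryTarget:
    """Recovery criterion: at least ``k`` correct copies of every allele,
    with probability at least ``confidence``."""

    k: int = 3
    confidence: float = 0.999

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError(
                f"confidence must lie strictly between 0 and 1, got {self.confidence}"
            )


@dataclass(frozen=True)
class CoverageResult:
    """Minimal total read count meeting a :class:`RecoveryTarget`."""

    profile: AlleleProfile
    target: RecoveryTarget
    n_min: int
    prob_at_n_min: float


class MonteCarloEstimate(NamedTuple):
    estimate: float
    std_error: float


class PInterval(NamedTuple):
    """Closed interval of per-read correct probabilities, on a grid."""

    lo: float
    hi: float


def _log_multinomial_prob(n: int, counts: Sequence[int], qs: np.ndarray,
                          q_rest: float) -> float:
    """log P(category counts == `counts`, remainder in a q_rest category)."""
    c = np.asarray(counts, dtype=float)
    rest = n - c.sum()
    log_coef = gammaln(n + 1) - gammaln(c + 1).sum() - gammaln(rest + 1)
    return float(log_coef + xlogy(c, qs).sum() + xlogy(rest, max(q_rest, 0.0)))


def _prob_all_below(n: int, q: np.ndarray, subset: tuple[int, ...], k: int) -> float:
    """P(every allele in `subset` has fewer than k copies among n reads).

    Marginalises the remaining categories into one with probability
    1 - sum(q[subset]); the sum has k^|subset| terms.
    """
    if not subset:
        return 1.0
    qs = q[list(subset)]
    q_rest = 1.0 - float(qs.sum())
    total = 0.0
    for counts in product(range(k), repeat=len(subset)):
        s = sum(counts)
        if s > n:
            continue
        if q_rest <= 0.0 and n - s > 0:
            continue  # remainder category impossible
        lp = _log_multinomial_prob(n, counts, qs, q_rest)
        if lp > -math.inf:
            total += math.exp(lp)
    return total


def recovery_probability(n: int, profile: AlleleProfile, k: int = 3) -> float:
    """Exact probability that all ``m`` alleles reach at least ``k`` correct
    copies among ``n`` total reads.

    For a single allele this equals the binomial upper tail ``P(X >= k)``
    with ``X ~ Binomial(n, p)``.  The computation is inclusion–exclusion
    over the shortfall events for any ``m``, with multinomial terms
    evaluated in log space; cost grows as ``k**m`` and is intended for small
    allele counts (``m <= 4`` or so — use :func:`mc_recovery` beyond that).
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    q = profile.q
    m = profile.m
    if n < m * k:
        return 0.0
    total = 0.0
    for r in range(m + 1):
        sign = -1.0 if r % 2 else 1.0
        for subset in combinations(range(m), r):
            total += sign * _prob_all_below(n, q, subset, k)
    return min(max(total, 0.0), 1.0)


def min_coverage(profile: AlleleProfile, target: RecoveryTarget = RecoveryTarget()
                 ) -> CoverageResult:
    """Smallest total read count ``n`` with
    ``recovery_probability(n) >= target.confidence``.

    Exploits monotonicity of the recovery probability in ``n``: bracket by
    doubling from the trivial lower bound ``m * k``, then bisect.

    Raises
    ------
    ValueError
        If ``p_correct == 0`` (the confidence is unreachable at any depth).
    """
    if profile.p_correct <= 0.0:
        raise ValueError("unreachable confidence: p_correct is 0")
    k, c = target.k, target.confidence
    lo = profile.m * k  # below this the probability is exactly 0
    if recovery_probability(lo, profile, k) >= c:
        return CoverageResult(profile, target, lo,
                              recovery_probability(lo, profile, k))
    hi = max(2 * lo, lo + 1)
    while recovery_probability(hi, profile, k) < c:
        lo = hi
        hi *= 2
        if hi > _MAX_COVERAGE_SEARCH:
            raise RuntimeError(
                f"coverage search exceeded {_MAX_COVERAGE_SEARCH} reads; "
                f"confidence {c} is practically unreachable for {profile}"
            )
    # invariant: prob(lo) < c <= prob(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if recovery_probability(mid, profile, k) >= c:
            hi = mid
        else:
            lo = mid
    return CoverageResult(profile, target, hi, recovery_probability(hi, profile, k))


def mc_recovery(n: int, profile: AlleleProfile, k: int = 3, reps: int = 10_000,
                seed: int | None = None) -> MonteCarloEstimate:
    """Monte-Carlo estimate of :func:`recovery_probability`.

    Draws ``reps`` multinomial samples of size ``n`` over the allele and
    error categories and reports the success fraction with its binomial
    standard error.  Deterministic for a fixed ``seed``; intended as an
    independent check on the exact computation and as the default route for
    many-allele profiles where inclusion–exclusion becomes expensive.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    q = profile.q
    pvals = np.append(q, max(1.0 - q.sum(), 0.0))
    pvals /= pvals.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, pvals, size=reps)
    ok = (counts[:, : profile.m] >= k).all(axis=1)
    est = float(ok.mean())
    se = math.sqrt(est * (1.0 - est) / reps)
    return MonteCarloEstimate(est, se)


def consistent_p_interval(n_printed: int, weights: Sequence[float],
                          target: RecoveryTarget = RecoveryTarget(),
                          grid_step: float = 1e-3) -> PInterval | None:
    """Grid interval of correct-read proportions ``p`` whose minimum coverage
    equals a given published value.

    ``min_coverage`` is non-increasing in ``p``, so the preimage of
    ``n_printed`` is contiguous; it is located by bisection on a ``p`` grid
    of resolution ``grid_step`` over (0, 1].  Returns ``None`` when no grid
    point maps to ``n_printed`` (including the impossible case
    ``n_printed < m * k``).
    """
    m = len(tuple(weights))
    if n_printed < m * target.k:
        return None
    n_grid = int(round(1.0 / grid_step))
    ps = np.arange(1, n_grid + 1) / n_grid  # grid over (0, 1], includes 1.0

    def nmin(p: float) -> int:
        return min_coverage(AlleleProfile(float(p), tuple(weights)), target).n_min

    # leftmost grid index with n_min <= n_printed (n_min non-increasing in p)
    lo_i, hi_i = 0, len(ps) - 1
    if nmin(ps[hi_i]) > n_printed:
        return None
    while lo_i < hi_i:
        mid = (lo_i + hi_i) // 2
        if nmin(ps[mid]) <= n_printed:
            hi_i = mid
        else:
            lo_i = mid + 1
    left = hi_i
    if nmin(ps[left]) != n_printed:
        return None
    # rightmost grid index with n_min >= n_printed
    lo_i, hi_i = left, len(ps) - 1
    while lo_i < hi_i:
        mid = (lo_i + hi_i + 1) // 2
        if nmin(ps[mid]) >= n_printed:
            lo_i = mid
        else:
            hi_i = mid - 1
    right = lo_i
    return PInterval(float(ps[left]), float(ps[right]))
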