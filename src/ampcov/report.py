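"""Per-enzyme summaries: coverage tables, condition comparison, curves.

Aggregates per-unit correct-read statistics into the report a practitioner
plans an experiment from: for each polymerase, the pooled proportion of
correct reads per marker system and the minimum coverage needed to recover
every allele with 99.9% confidence — for a haplotype, for two alleles
amplifying equally, and for two alleles where one amplifies half as well as
the other.  Enzymes that never amplified are flagged ``n.a.``; those with
too few reads (<= 10 pooled) are flagged ``i.d.`` (insufficient data).

The effect of cycling conditions on correctness is assessed with a
stratified permutation test on unit-level proportions (strata =
system x enzyme x individual), a self-contained alternative to mixed-model
fits which is calibrated in this package's test suite.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import CorrectReadStats, INCLUSION_MIN_READS, pool_stats
from .recovery import AlleleProfile, CoverageResult, RecoveryTarget, \
    min_coverage, recovery_probability

__all__ = [
    "EnzymeSummary",
    "ConditionComparison",
    "build_coverage_table",
    "coverage_table_frame",
    "compare_conditions",
    "probability_curves",
    "plot_probability_curves",
]

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NO_AMPLIFICATION = "n.a."
STATUS_INSUFFICIENT = "i.d."

#: Default bias for the "unequal amplification" column: one allele yields
#: twice as many products as the other.
DEFAULT_BIAS_WEIGHTS = (2.0, 1.0)


@dataclass
class EnzymeSummary:
    """Pooled statistics and coverage requirements for one enzyme in one
    marker system (conditions pooled)."""

    enzyme: str
    system: str
    condition: str
    pooled_p: float | None
    n_units: int
    n_reads: int
    status: str
    coverage_equal: CoverageResult | None = None
    coverage_unequal: CoverageResult | None = None


def build_coverage_table(stats: Iterable[CorrectReadStats],
                         target: RecoveryTarget = RecoveryTarget(),
                         enzymes: Sequence[str] | None = None,
                         systems: Sequence[str] | None = None,
                         bias_weights: tuple[float, float] = DEFAULT_BIAS_WEIGHTS,
                         ) -> list[EnzymeSummary]:
    """Pool units per enzyme x system (standard and modified conditions
    combined) and compute minimum coverages.

    For the haplotype system the single coverage number uses weights ``(1,)``
    (stored in ``coverage_equal``); for the two-allele system both the
    equal-amplification ``(1, 1)`` and biased ``bias_weights`` coverages are
    computed.  The multigene system gets pooled proportions only (its allele
    count varies per individual).  Enzymes present in the roster but with no
    reads for a system are flagged n.a.; pooled read counts of 10 or fewer
    are flagged i.d.
    """
    stats = list(stats)
    grouped: dict[tuple[str, str], list[CorrectReadStats]] = defaultdict(list)
    for s in stats:
        grouped[(s.unit.enzyme, s.unit.system)].append(s)
    enzyme_roster = list(enzymes) if enzymes is not None else \
        sorted({s.unit.enzyme for s in stats})
    system_roster = list(systems) if systems is not None else \
        sorted({s.unit.system for s in stats})
    out: list[EnzymeSummary] = []
    for enzyme in enzyme_roster:
        for system in system_roster:
            members = [s for s in grouped.get((enzyme, system), ())
                       if s.n_reads > 0]
            n_reads = sum(s.n_reads for s in members)
            if not members:
                out.append(EnzymeSummary(enzyme, system, "pooled", None, 0, 0,
                                         STATUS_NO_AMPLIFICATION))
                continue
            pooled = pool_stats(members, by=("system", "enzyme"))[0]
            if n_reads <= INCLUSION_MIN_READS:
                out.append(EnzymeSummary(enzyme, system, "pooled",
                                         pooled.p_hat, len(members), n_reads,
                                         STATUS_INSUFFICIENT))
                continue
            summary = EnzymeSummary(enzyme, system, "pooled", pooled.p_hat,
                                    len(members), n_reads, STATUS_OK)
            if pooled.p_hat > 0:
                if system == "simple":
                    summary.coverage_equal = min_coverage(
                        AlleleProfile(pooled.p_hat, (1.0,)), target)
                elif system == "two_allele":
                    summary.coverage_equal = min_coverage(
                        AlleleProfile(pooled.p_hat, (1.0, 1.0)), target)
                    summary.coverage_unequal = min_coverage(
                        AlleleProfile(pooled.p_hat, tuple(bias_weights)), target)
            out.append(summary)
    return out


def coverage_table_frame(summaries: Iterable[EnzymeSummary]) -> pd.DataFrame:
    """Pivot summaries into one row per enzyme with columns for the
    haplotype coverage and the two-allele equal / unequal coverages, using
    the n.a. / i.d. flags in place of numbers.  Rows are ordered by
    haplotype coverage (flagged rows last)."""
    per_enzyme: dict[str, dict[str, str]] = defaultdict(dict)
    order_key: dict[str, float] = {}
    for s in summaries:
        def fmt(cov: CoverageResult | None) -> str:
            if s.status != STATUS_OK:
                return s.status
            return str(cov.n_min) if cov is not None else ""
        row = per_enzyme[s.enzyme]
        if s.system == "simple":
            row["haplotype"] = fmt(s.coverage_equal)
            # numeric coverages first, then i.d., then n.a.
            if s.status == STATUS_OK and s.coverage_equal:
                order_key[s.enzyme] = float(s.coverage_equal.n_min)
            elif s.status == STATUS_INSUFFICIENT:
                order_key[s.enzyme] = 1e17
            else:
                order_key[s.enzyme] = 1e18
        elif s.system == "two_allele":
            row["two_allele_equal"] = fmt(s.coverage_equal)
            row["two_allele_unequal"] = fmt(s.coverage_unequal)
        else:
            row[f"{s.system}_p"] = (f"{s.pooled_p:.3f}"
                                    if s.status == STATUS_OK else s.status)
    rows = [{"enzyme": e, **cols} for e, cols in per_enzyme.items()]
    df = pd.DataFrame(rows)
    df["_order"] = [order_key.get(e, 1e18) for e in df["enzyme"]]
    df = df.sort_values(["_order", "enzyme"]).drop(columns="_order")
    return df.reset_index(drop=True)


@dataclass
class ConditionComparison:
    """Read-weighted difference in correct proportion (b minus a) and its
    stratified-permutation two-sided p-value."""

    observed_diff: float
    p_value: float
    n_strata_used: int
    n_strata_dropped: int
    reps: int


def compare_conditions(stats_a: Iterable[CorrectReadStats],
                       stats_b: Iterable[CorrectReadStats],
                       reps: int = 10_000, seed: int | None = None,
                       ) -> ConditionComparison:
    """Permutation test for a cycling-condition effect on correctness.

    The statistic is the difference between conditions in the read-weighted
    pooled proportion of correct reads (sum correct / sum reads), over
    strata defined by (system, enzyme, individual) that contain units from
    both conditions; strata with only one condition are dropped with a
    logged note.  Under the null, condition labels are exchangeable within a
    stratum, so labels are permuted within strata; the two-sided p-value
    uses the add-one convention (observed counted among the permutations).
    """
    stats_a, stats_b = list(stats_a), list(stats_b)
    if reps < 100:
        raise ValueError(f"reps must be >= 100, got {reps}")
    if not stats_a or not stats_b:
        raise ValueError("both condition collections must be non-empty")

    def stratum(s: CorrectReadStats) -> tuple[str, str, str]:
        return (s.unit.system, s.unit.enzyme, s.unit.individual)

    strata: dict[tuple, tuple[list, list]] = defaultdict(lambda: ([], []))
    for s in stats_a:
        strata[stratum(s)][0].append(s)
    for s in stats_b:
        strata[stratum(s)][1].append(s)
    kept, dropped = [], 0
    for key, (ga, gb) in sorted(strata.items()):
        if ga and gb:
            kept.append((ga, gb))
        else:
            dropped += 1
            logger.info("stratum %s has only one condition; dropped", key)
    if not kept:
        raise ValueError("no stratum contains both conditions")

    units = [s for ga, gb in kept for s in ga + gb]
    n_reads = np.array([s.n_reads for s in units], dtype=float)
    n_correct = np.array([s.n_correct for s in units], dtype=float)
    labels = []
    bounds = []
    pos = 0
    for ga, gb in kept:
        labels.extend([False] * len(ga) + [True] * len(gb))
        bounds.append((pos, pos + len(ga) + len(gb)))
        pos += len(ga) + len(gb)
    labels = np.array(labels, dtype=bool)

    def statistic(lab_matrix: np.ndarray) -> np.ndarray:
        # lab_matrix: (reps, units) booleans for condition b
        reads_b = lab_matrix @ n_reads
        corr_b = lab_matrix @ n_correct
        reads_a = (~lab_matrix) @ n_reads
        corr_a = (~lab_matrix) @ n_correct
        return corr_b / reads_b - corr_a / reads_a

    observed = float(statistic(labels[None, :])[0])

    rng = np.random.default_rng(seed)
    perm = np.empty((reps, len(units)), dtype=bool)
    for start, stop in bounds:
        block = labels[start:stop]
        # shuffle labels within the stratum independently per replicate
        keys = rng.random((reps, stop - start))
        idx = np.argsort(keys, axis=1)
        perm[:, start:stop] = block[idx]
    perm_stats = statistic(perm)
    p = (1 + int(np.sum(np.abs(perm_stats) >= abs(observed) - 1e-12))) / (reps + 1)
    return ConditionComparison(observed, float(p), len(kept), dropped, reps)


def probability_curves(profiles: Mapping[str, AlleleProfile], k: int = 3,
                       n_max: int = 100) -> pd.DataFrame:
    """Tabulate the recovery probability for n = k .. n_max per labelled
    profile — the data behind probability-vs-coverage curve panels
    (haplotype / equal amplification / biased amplification)."""
    if n_max < k:
        raise ValueError(f"n_max {n_max} must be >= k {k}")
    rows = []
    for label, profile in profiles.items():
        for n in range(k, n_max + 1):
            rows.append({"profile": label, "n": n,
                         "probability": recovery_probability(n, profile, k)})
    return pd.DataFrame(rows)


def plot_probability_curves(curves: pd.DataFrame, path: str) -> None:
    """Thin optional plotting layer over :func:`probability_curves` output
    (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, sub in curves.groupby("profile"):
        ax.plot(sub["n"], sub["probability"], label=str(label))
    ax.set_xlabel("total reads (coverage)")
    ax.set_ylabel("P(every allele has ≥ k correct reads)")
    ax.axhline(0.999, color="grey", lw=0.8, ls="--")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
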