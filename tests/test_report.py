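"""Coverage tables, n.a./i.d. flags, permutation comparison, curves."""

import numpy as np
import pytest

from ampcov.amplicon_io import ExperimentalUnit
from ampcov.classify import CorrectReadStats
from ampcov.recovery import AlleleProfile, RecoveryTarget
from ampcov.report import (
    STATUS_INSUFFICIENT,
    STATUS_NO_AMPLIFICATION,
    STATUS_OK,
    build_coverage_table,
    compare_conditions,
    coverage_table_frame,
    probability_curves,
)


def unit_stats(system, enzyme, condition, individual, n_reads, n_correct):
    unit = ExperimentalUnit(system, enzyme, condition, individual)
    counts = {"a1": n_correct} if n_correct else {}
    return CorrectReadStats(unit, n_reads, n_correct, counts)


class TestBuildCoverageTable:
    def test_haplotype_coverage_for_best_enzyme_proportion(self):
        # pooled p = 0.88 for a haplotype system -> 7 reads at k=3, c=99.9%
        stats = [unit_stats("simple", "Phusion", "standard", "ind1", 100, 88)]
        rows = build_coverage_table(stats)
        assert rows[0].status == STATUS_OK
        assert rows[0].pooled_p == pytest.approx(0.88)
        assert rows[0].coverage_equal.n_min == 7
        assert rows[0].coverage_unequal is None

    def test_two_allele_gets_equal_and_biased_columns(self):
        stats = [unit_stats("two_allele", "E", "standard", "i", 200, 120),
                 unit_stats("two_allele", "E", "modified", "i", 100, 60)]
        row = build_coverage_table(stats)[0]
        assert row.n_reads == 300  # conditions pooled
        assert row.coverage_equal is not None
        assert row.coverage_unequal is not None
        assert row.coverage_equal.n_min <= row.coverage_unequal.n_min

    def test_missing_enzyme_flagged_na(self):
        stats = [unit_stats("simple", "E1", "standard", "i", 100, 80)]
        rows = build_coverage_table(stats, enzymes=["E1", "Ghost"])
        by_enzyme = {r.enzyme: r for r in rows}
        assert by_enzyme["Ghost"].status == STATUS_NO_AMPLIFICATION
        assert by_enzyme["Ghost"].coverage_equal is None

    def test_ten_or_fewer_reads_flagged_insufficient(self):
        stats = [unit_stats("simple", "E1", "standard", "i", 9, 9)]
        row = build_coverage_table(stats)[0]
        assert row.status == STATUS_INSUFFICIENT
        assert row.coverage_equal is None
        # pooled over two small units crossing the threshold -> computed
        stats.append(unit_stats("simple", "E1", "modified", "i", 9, 9))
        row = build_coverage_table(stats)[0]
        assert row.status == STATUS_OK

    def test_bias_column_dominates_equal_column_for_every_enzyme(self):
        rng = np.random.default_rng(0)
        stats = []
        for i, p in enumerate((0.1, 0.35, 0.6, 0.92)):
            n = 500
            stats.append(unit_stats("two_allele", f"E{i}", "standard", "i",
                                    n, int(round(p * n))))
        for row in build_coverage_table(stats):
            assert row.coverage_equal.n_min <= row.coverage_unequal.n_min

    def test_frame_layout_and_ordering(self):
        stats = [
            unit_stats("simple", "Good", "standard", "i", 1000, 900),
            unit_stats("simple", "Bad", "standard", "i", 1000, 520),
            unit_stats("simple", "Tiny", "standard", "i", 5, 5),
            unit_stats("two_allele", "Good", "standard", "i", 1000, 800),
        ]
        df = coverage_table_frame(build_coverage_table(
            stats, enzymes=["Good", "Bad", "Tiny", "Ghost"]))
        assert list(df["enzyme"]) == ["Good", "Bad", "Tiny", "Ghost"]
        assert df.set_index("enzyme").loc["Tiny", "haplotype"] == "i.d."
        assert df.set_index("enzyme").loc["Ghost", "haplotype"] == "n.a."
        good = df.set_index("enzyme").loc["Good"]
        assert int(good["haplotype"]) == 7  # p=0.9 haplotype
        assert int(good["two_allele_equal"]) <= int(good["two_allele_unequal"])


def paired_stats(rng, n_strata, n_reads, p_a, p_b):
    a, b = [], []
    for i in range(n_strata):
        ind = f"ind{i}"
        a.append(unit_stats("simple", "E", "standard", ind, n_reads,
                            int(rng.binomial(n_reads, p_a))))
        b.append(unit_stats("simple", "E", "modified", ind, n_reads,
                            int(rng.binomial(n_reads, p_b))))
    return a, b


class TestCompareConditions:
    def test_identical_collections_give_zero_diff_p_one(self):
        rng = np.random.default_rng(1)
        a, _ = paired_stats(rng, 5, 200, 0.6, 0.6)
        b = [CorrectReadStats(
            ExperimentalUnit(s.unit.system, s.unit.enzyme, "modified",
                             s.unit.individual),
            s.n_reads, s.n_correct, dict(s.per_allele_counts)) for s in a]
        result = compare_conditions(a, b, reps=500, seed=0)
        assert result.observed_diff == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0, abs=0.01)

    def test_known_effect_detected(self):
        rng = np.random.default_rng(2)
        a, b = paired_stats(rng, 10, 2000, 0.5, 0.575)
        result = compare_conditions(a, b, reps=2000, seed=3)
        assert result.observed_diff == pytest.approx(0.075, abs=0.02)
        assert result.p_value < 0.01

    def test_single_condition_stratum_dropped(self):
        rng = np.random.default_rng(3)
        a, b = paired_stats(rng, 4, 500, 0.5, 0.5)
        a.append(unit_stats("simple", "E", "standard", "lonely", 500, 250))
        result = compare_conditions(a, b, reps=200, seed=1)
        assert result.n_strata_dropped == 1
        assert result.n_strata_used == 4

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(4)
        a, b = paired_stats(rng, 5, 300, 0.4, 0.5)
        r1 = compare_conditions(a, b, reps=300, seed=9)
        r2 = compare_conditions(a, b, reps=300, seed=9)
        assert r1 == r2

    def test_too_few_reps_rejected(self):
        rng = np.random.default_rng(5)
        a, b = paired_stats(rng, 3, 100, 0.5, 0.5)
        with pytest.raises(ValueError, match="reps"):
            compare_conditions(a, b, reps=50)


class TestProbabilityCurves:
    def test_tabulation_and_monotonicity(self):
        profiles = {
            "haplotype": AlleleProfile(0.88),
            "equal": AlleleProfile(0.5, (1.0, 1.0)),
            "biased": AlleleProfile(0.5, (2.0, 1.0)),
        }
        df = probability_curves(profiles, k=3, n_max=60)
        assert set(df["profile"]) == set(profiles)
        for _, sub in df.groupby("profile"):
            probs = sub.sort_values("n")["probability"].to_numpy()
            assert np.all(np.diff(probs) >= -1e-12)
        hap = df[df["profile"] == "haplotype"].set_index("n")
        assert hap.loc[7, "probability"] >= 0.999  # coverage 7 is enough

    def test_n_max_below_k_rejected(self):
        with pytest.raises(ValueError):
            probability_curves({"x": AlleleProfile(0.5)}, k=3, n_max=2)
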