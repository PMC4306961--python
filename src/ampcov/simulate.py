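"""Synthetic tailed-amplicon reads with a controllable PCR error structure.

Emulates what a pyrosequencing run of a two-round tailed-amplicon library
looks like after basecalling, so the demultiplex → classify → coverage
pipeline can be exercised offline: reads carry the full
adaptor+key | MID | tail | primer | insert | ... architecture in a random
orientation, and the insert is corrupted by

* per-base substitutions,
* single-base indels at homopolymer runs (length >= 3 — the dominant
  446/454-style artefact; the loci modelled here have homopolymers up to
  5 bp),
* single-crossover chimeras between two distinct template alleles, the
  PCR artefact formed when a partially extended strand primes on a related
  allele in a later cycle,
* allele amplification bias via per-allele template weights.

Errors touch the insert only; MIDs, tails and primers are emitted intact so
that filtering and correctness are decoupled (a read with an insert error
still demultiplexes, then scores incorrect).  `calibrate_profile` back-solves
the substitution rate so the expected proportion of unaltered reads matches
a target, letting a profile stand in for an enzyme of known fidelity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .amplicon_io import (
    IUPAC_CODES,
    AmpliconDesign,
    ExperimentalUnit,
    SampleSheet,
    reverse_complement,
)
from .classify import ReferencePanel

__all__ = [
    "EnzymeErrorProfile",
    "TruthRecord",
    "simulate_unit",
    "calibrate_profile",
    "homopolymer_runs",
    "default_designs",
    "random_panel",
    "random_mids",
    "Experiment",
    "miniature_experiment",
]

_BASES = "ACGT"
_HOMOPOLYMER_RE = re.compile(r"(.)\1{2,}")


@dataclass(frozen=True)
class EnzymeErrorProfile:
    """Mechanistic error knobs standing in for one polymerase's fidelity.

    ``target_p_correct`` is the intended expected proportion of reads whose
    insert is emitted unaltered; use :func:`calibrate_profile` to adjust
    ``substitution_rate`` so the mechanism achieves it.  ``allele_weights``
    bias template choice (``None`` = equal).
    """

    label: str
    target_p_correct: float
    substitution_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    chimera_fraction: float = 0.0
    allele_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("target_p_correct", "substitution_rate",
                     "homopolymer_indel_rate", "chimera_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.allele_weights is not None:
            w = tuple(float(x) for x in self.allele_weights)
            if any(x <= 0 for x in w):
                raise ValueError("allele_weights must be positive")
            object.__setattr__(self, "allele_weights", w)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read.  ``is_correct`` reflects the
    *emitted* insert (an error that regenerates a reference still counts as
    correct), so it is computed post hoc, not from intent."""

    read_id: str
    unit: ExperimentalUnit
    source_allele: str  # allele id, "chimera", or "error"
    is_correct: bool


def homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of each homopolymer run of length >= 3."""
    return [(m.start(), m.end() - m.start())
            for m in _HOMOPOLYMER_RE.finditer(seq)]


def _concrete(seq: str) -> str:
    """Replace degenerate IUPAC codes by a fixed concrete base (the first of
    the expansion), so emitted primers still IUPAC-match the design."""
    return "".join(sorted(IUPAC_CODES[c])[0] for c in seq)


def _mutate_insert(insert: str, profile: EnzymeErrorProfile,
                   rng: np.random.Generator) -> str:
    seq = insert
    if profile.substitution_rate > 0:
        chars = list(seq)
        hit = np.flatnonzero(rng.random(len(chars)) < profile.substitution_rate)
        for i in hit:
            others = _BASES.replace(chars[i], "")
            chars[i] = others[rng.integers(len(others))]
        seq = "".join(chars)
    if profile.homopolymer_indel_rate > 0:
        runs = homopolymer_runs(seq)
        # apply right-to-left so earlier indices stay valid
        for start, length in reversed(runs):
            if rng.random() < profile.homopolymer_indel_rate:
                if rng.random() < 0.5:
                    seq = seq[:start] + seq[start] + seq[start:]
                else:
                    seq = seq[:start] + seq[start + 1:]
    return seq


def simulate_unit(design: AmpliconDesign, alleles: Mapping[str, str],
                  profile: EnzymeErrorProfile, n_reads: int, mid: str,
                  seed: int, unit: ExperimentalUnit | None = None,
                  ) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Simulate one experimental unit's reads.

    Each read picks a template allele with probability proportional to the
    profile's allele weights; with probability ``chimera_fraction`` the
    insert is replaced by a single-crossover chimera of two distinct alleles
    (breakpoint uniform over internal positions); substitutions and
    homopolymer indels are then applied; finally the insert is wrapped in
    the full two-round amplicon structure and emitted in a random
    orientation.  Deterministic for a fixed seed.

    Returns (FASTA-ready (id, sequence) pairs, truth records).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if not alleles:
        raise ValueError("alleles must be non-empty")
    if len(mid) != design.mid_length:
        raise ValueError(
            f"MID length {len(mid)} does not match design ({design.mid_length})")
    allele_ids = sorted(alleles)
    seqs = [alleles[a].upper() for a in allele_ids]
    if profile.chimera_fraction > 0 and len(set(seqs)) < 2:
        raise ValueError("chimera simulation requires at least two distinct alleles")
    if profile.allele_weights is not None and len(profile.allele_weights) != len(allele_ids):
        raise ValueError("allele_weights length does not match allele count")
    w = np.asarray(profile.allele_weights
                   if profile.allele_weights is not None
                   else [1.0] * len(allele_ids), dtype=float)
    w /= w.sum()
    if unit is None:
        unit = ExperimentalUnit("simple", profile.label, "standard", "anon")

    mid = mid.upper()
    prefix = (design.adaptor_forward + mid + design.forward_tail
              + _concrete(design.forward_primer))
    suffix = (reverse_complement(_concrete(design.reverse_primer))
              + reverse_complement(design.reverse_tail)
              + reverse_complement(mid)
              + reverse_complement(design.adaptor_reverse))
    reference = set(seqs)

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    for i in range(n_reads):
        a = int(rng.choice(len(allele_ids), p=w))
        source = allele_ids[a]
        insert = seqs[a]
        if profile.chimera_fraction > 0 and rng.random() < profile.chimera_fraction:
            choices = [b for b in range(len(allele_ids))
                       if seqs[b] != seqs[a]]
            b = int(choices[rng.integers(len(choices))])
            min_len = min(len(seqs[a]), len(seqs[b]))
            bp = int(rng.integers(1, min_len))  # internal breakpoint
            insert = seqs[a][:bp] + seqs[b][bp:]
            source = "chimera"
        mutated = _mutate_insert(insert, profile, rng)
        if source != "chimera" and mutated != insert:
            source = "error"
        read = prefix + mutated + suffix
        if rng.random() < 0.5:
            read = reverse_complement(read)
        read_id = f"{mid}_{i:05d}"
        reads.append((read_id, read))
        truths.append(TruthRecord(read_id, unit, source, mutated in reference))
    return reads, truths


def calibrate_profile(profile: EnzymeErrorProfile, alleles: Mapping[str, str]
                      ) -> EnzymeErrorProfile:
    """Back-solve the substitution rate so the expected fraction of unaltered
    reads equals ``target_p_correct``.

    The survival probability of a read from allele ``a`` (length ``L_a``,
    ``s_a`` homopolymer sites) is

        (1 - chimera_fraction) * (1 - sub)**L_a * (1 - indel)**s_a

    and the expectation weights alleles by the profile's template weights.
    Chimera and indel rates are kept fixed; only the substitution rate is
    solved for.  Raises ``ValueError`` when the target is infeasible (the
    fixed rates alone already destroy too many reads).
    """
    target = profile.target_p_correct
    if target == 1.0:
        return replace(profile, substitution_rate=0.0,
                       homopolymer_indel_rate=0.0, chimera_fraction=0.0)
    ids = sorted(alleles)
    w = np.asarray(profile.allele_weights
                   if profile.allele_weights is not None
                   else [1.0] * len(ids), dtype=float)
    w /= w.sum()
    lengths = np.array([len(alleles[a]) for a in ids], dtype=float)
    sites = np.array([len(homopolymer_runs(alleles[a].upper())) for a in ids],
                     dtype=float)
    base = 1.0 - profile.chimera_fraction

    def expected_survival(sub: float) -> float:
        return float(base * np.sum(
            w * (1.0 - sub) ** lengths
            * (1.0 - profile.homopolymer_indel_rate) ** sites))

    if expected_survival(0.0) < target:
        raise ValueError(
            f"target_p_correct={target} infeasible: chimera/indel rates alone "
            f"leave expected survival {expected_survival(0.0):.4f}")
    if target == 0.0:
        return replace(profile, substitution_rate=1.0)
    sub = brentq(lambda s: expected_survival(s) - target, 0.0, 1.0 - 1e-12,
                 xtol=1e-15)
    return replace(profile, substitution_rate=float(sub))


# ---------------------------------------------------------------------------
# Bundled miniature experiment: three marker systems of increasing
# complexity, several enzyme fidelity profiles, two cycling conditions.
# ---------------------------------------------------------------------------

_FORWARD_TAIL = "gttttcccagtcacgac"   # M13 forward tail (round-1 primer 5' add-on)
_REVERSE_TAIL = "aacagctatgaccatg"    # M13 reverse tail
_ADAPTOR_FWD = "CGTATCGCCTCCCTCGCGCCATCAG"  # Lib-A adaptor A, ends in TCAG key
_ADAPTOR_REV = "CTATGCGCCTTGCCAGCCCGCTCAG"  # Lib-A adaptor B


def default_designs() -> dict[str, AmpliconDesign]:
    """One tailed-amplicon design per marker system.

    simple: canid mtDNA control-region 5' end (Thr-L / ddl5, 168–172 bp
    insert); two_allele: equid MHC class II exon 2 (Be3 / Be4, degenerate,
    ~257 bp); multigene: equid MHC class I exon 3 (PpLAa2U270 / Ppa2L542,
    ~184 bp).  Keyed by the system label the design serves.
    """
    common = dict(forward_tail=_FORWARD_TAIL, reverse_tail=_REVERSE_TAIL,
                  adaptor_forward=_ADAPTOR_FWD, adaptor_reverse=_ADAPTOR_REV,
                  mid_length=10, key_length=4)
    return {
        "simple": AmpliconDesign(
            locus_name="mtDNA_CR",
            forward_primer="GAATTCCCCGGTCTTGTAAACC",
            reverse_primer="CATTAATGCACGACGTACATAGG",
            insert_length_range=(168, 172), **common),
        "two_allele": AmpliconDesign(
            locus_name="MHCII_ex2",
            forward_primer="GGGTCTCACACCYKCCAG",
            reverse_primer="GMGCWGCAGSGTCTCYTT",
            insert_length_range=(252, 262), **common),
        "multigene": AmpliconDesign(
            locus_name="MHCI_ex3",
            forward_primer="GCTTCTCATCCTAGTTCCCTT",
            reverse_primer="GCCTAGGAGTGCAGCAGA",
            insert_length_range=(179, 189), **common),
    }


_ALLELES_PER_SYSTEM = {"simple": 1, "two_allele": 2, "multigene": 3}
_NOMINAL_INSERT = {"simple": 170, "two_allele": 257, "multigene": 184}


def _random_allele(rng: np.random.Generator, length: int) -> str:
    # seed a 4-bp homopolymer so the indel channel has a site to act on
    seq = "".join(rng.choice(list(_BASES), size=length))
    pos = int(rng.integers(0, length - 4))
    base = seq[pos]
    return seq[:pos] + base * 4 + seq[pos + 4:]


def random_panel(systems: Iterable[str], individuals: Sequence[str],
                 seed: int, designs: Mapping[str, AmpliconDesign] | None = None,
                 ) -> ReferencePanel:
    """Deterministic random reference alleles for each individual and system
    (1 allele for simple, 2 for two_allele, 3 for multigene), at the nominal
    insert length of each locus."""
    designs = designs or default_designs()
    rng = np.random.default_rng(seed)
    panel = ReferencePanel()
    for system in systems:
        locus = designs[system].locus_name
        length = _NOMINAL_INSERT[system]
        for ind in individuals:
            seen: set[str] = set()
            for j in range(_ALLELES_PER_SYSTEM[system]):
                while True:
                    allele = _random_allele(rng, length)
                    if allele not in seen:
                        seen.add(allele)
                        break
                panel.add(ind, locus, f"{ind}_a{j + 1}", allele)
    return panel


def random_mids(n: int, seed: int, length: int = 10,
                min_distance: int = 3) -> list[str]:
    """n distinct MID barcodes with pairwise Hamming distance >= 3 (matching
    the design property of commercial MID sets), deterministic per seed."""
    rng = np.random.default_rng(seed)
    mids: list[str] = []
    while len(mids) < n:
        cand = "".join(rng.choice(list(_BASES), size=length))
        if all(sum(a != b for a, b in zip(cand, m)) >= min_distance
               for m in mids):
            mids.append(cand)
    return mids


@dataclass
class Experiment:
    """A simulated multi-system run: mixed reads plus everything needed to
    analyse them and to check the analysis against ground truth."""

    designs: dict[str, AmpliconDesign]
    panel: ReferencePanel
    sheet: SampleSheet
    reads: list[tuple[str, str]]
    truth: list[TruthRecord]
    profiles: dict[str, EnzymeErrorProfile]


def miniature_experiment(seed: int,
                         n_reads_per_unit: int = 120,
                         systems: Sequence[str] = ("simple", "two_allele",
                                                   "multigene"),
                         individuals: Sequence[str] = ("ind1", "ind2", "ind3"),
                         conditions: Sequence[str] = ("standard", "modified"),
                         profiles: Mapping[str, EnzymeErrorProfile] | None = None,
                         calibrate: bool = True,
                         trace_enzyme: str | None = "TraceE",
                         trace_reads: int = 8,
                         ) -> Experiment:
    """Simulate a miniature version of the study design.

    Four enzyme fidelity profiles by default: high / medium / low expected
    correctness (0.9 / 0.5 / 0.1, spanning the per-enzyme range seen in
    practice) plus one enzyme that never amplifies (zero reads everywhere,
    exercising the "did not amplify" report flag).  A fifth trace-yield
    enzyme contributes a single unit of ``trace_reads`` reads in the first
    system, exercising the insufficient-data flag (10 reads or fewer
    pooled).  All randomness derives from ``seed``.
    """
    designs = default_designs()
    designs = {s: designs[s] for s in systems}
    panel = random_panel(systems, individuals, seed=seed)
    if profiles is None:
        profiles = {
            "HiFiA": EnzymeErrorProfile("HiFiA", target_p_correct=0.9,
                                        substitution_rate=1e-3),
            "MidB": EnzymeErrorProfile("MidB", target_p_correct=0.5,
                                       substitution_rate=1e-3,
                                       homopolymer_indel_rate=0.02),
            "LowC": EnzymeErrorProfile("LowC", target_p_correct=0.1,
                                       substitution_rate=1e-2,
                                       chimera_fraction=0.05),
            "NoAmpD": EnzymeErrorProfile("NoAmpD", target_p_correct=0.9),
        }
    sheet = SampleSheet()
    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    amplifying = [lab for lab in profiles if lab != "NoAmpD"]
    n_per_enzyme = len(systems) * len(conditions) * len(individuals)
    n_units = len(amplifying) * n_per_enzyme
    n_extra = n_per_enzyme if "NoAmpD" in profiles else 0
    n_trace = 1 if trace_enzyme else 0
    mids = random_mids(n_units + n_extra + n_trace, seed=seed + 1)
    root = np.random.default_rng(seed)
    mid_iter = iter(mids)

    def add_unit(system: str, enzyme: str, condition: str, ind: str,
                 profile: EnzymeErrorProfile, n: int) -> None:
        design = designs[system]
        unit = ExperimentalUnit(system, enzyme, condition, ind)
        mid = next(mid_iter)
        sheet.add(mid, design.locus_name, unit)
        alleles = panel.alleles(ind, design.locus_name)
        prof = profile
        if profile.chimera_fraction > 0 and len(alleles) < 2:
            prof = replace(profile, chimera_fraction=0.0)
        if calibrate:
            prof = calibrate_profile(prof, alleles)
        unit_seed = int(root.integers(2 ** 31))
        unit_reads, unit_truth = simulate_unit(
            design, alleles, prof, n, mid, unit_seed, unit=unit)
        reads.extend(unit_reads)
        truth.extend(unit_truth)

    for system in systems:
        for enzyme in amplifying:
            for condition in conditions:
                for ind in individuals:
                    add_unit(system, enzyme, condition, ind,
                             profiles[enzyme], n_reads_per_unit)
    if trace_enzyme:
        add_unit(systems[0], trace_enzyme, conditions[0], individuals[0],
                 profiles[amplifying[0]], trace_reads)
    # sheet entries for the non-amplifying enzyme so it is a known unit with
    # zero reads rather than an absent one
    if "NoAmpD" in profiles:
        it = iter(mids[n_units + n_trace:])
        for system in systems:
            for condition in conditions:
                for ind in individuals:
                    sheet.add(next(it), designs[system].locus_name,
                              ExperimentalUnit(system, "NoAmpD", condition, ind))
    rng = np.random.default_rng(seed + 3)
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return Experiment(designs, panel, sheet, reads, truth,
                      dict(profiles))
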