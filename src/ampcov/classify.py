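"""Read correctness against known reference alleles.

A trimmed read is *correct* when it is character-identical to one of the
reference alleles of its individual at the locus (either strand); anything
else — substitutions, homopolymer indels, chimeras — is incorrect.  The
per-unit proportion of correct reads p̂ = n_correct / n_reads is the
quantity that drives coverage planning, and a unit enters downstream
statistics only when it has more than 10 reads.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .amplicon_io import DemuxRecord, ExperimentalUnit, reverse_complement, write_fasta

__all__ = [
    "INCLUSION_MIN_READS",
    "ReferencePanel",
    "CorrectReadStats",
    "classify_reads",
    "pool_stats",
    "stats_frame",
    "stats_from_frame",
]

#: A unit is included in statistics only with strictly more than this many reads.
INCLUSION_MIN_READS = 10


@dataclass
class ReferencePanel:
    """Known allele sequences per (individual, locus).

    One allele for a haplotype system, one or two for a single-copy nuclear
    gene, one or more for a multigene family.  Sequences are stored
    upper-cased; alleles within one entry must be pairwise distinct.
    """

    entries: dict[tuple[str, str], dict[str, str]] = field(default_factory=dict)

    def add(self, individual: str, locus: str, allele_id: str, seq: str) -> None:
        if not seq:
            raise ValueError("allele sequence must be non-empty")
        entry = self.entries.setdefault((individual, locus), {})
        seq = seq.upper()
        if allele_id in entry and entry[allele_id] != seq:
            raise ValueError(f"conflicting sequences for allele {allele_id}")
        if seq in entry.values() and entry.get(allele_id) != seq:
            raise ValueError(
                f"duplicate allele sequence for ({individual}, {locus})")
        entry[allele_id] = seq

    def alleles(self, individual: str, locus: str) -> dict[str, str]:
        return self.entries[(individual, locus)]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferencePanel":
        """Load from FASTA with headers ``individual|locus|allele_id``."""
        from Bio import SeqIO

        panel = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"reference header {rec.id!r} is not individual|locus|allele_id")
            panel.add(parts[0], parts[1], parts[2], str(rec.seq))
        return panel

    def to_fasta(self, path: str | Path) -> None:
        records = [
            (f"{ind}|{locus}|{allele_id}", seq)
            for (ind, locus), alleles in sorted(self.entries.items())
            for allele_id, seq in sorted(alleles.items())
        ]
        write_fasta(records, path)


@dataclass
class CorrectReadStats:
    """Read counts for one experimental unit (or one pooled key)."""

    unit: ExperimentalUnit
    n_reads: int
    n_correct: int
    per_allele_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_correct > self.n_reads or self.n_correct < 0:
            raise ValueError(
                f"n_correct {self.n_correct} outside [0, n_reads={self.n_reads}]")
        if sum(self.per_allele_counts.values()) != self.n_correct:
            raise ValueError("per-allele counts must sum to n_correct")

    @property
    def p_hat(self) -> float:
        """Observed proportion of correct reads (0 for an empty unit)."""
        return self.n_correct / self.n_reads if self.n_reads else 0.0

    @property
    def included(self) -> bool:
        """Inclusion filter: strictly more than 10 reads."""
        return self.n_reads > INCLUSION_MIN_READS


def _identity_lookup(alleles: Mapping[str, str]) -> dict[str, str]:
    """sequence (either strand) -> allele id; ties go to the first allele id
    in sorted order and are never overwritten."""
    lookup: dict[str, str] = {}
    for allele_id in sorted(alleles):
        seq = alleles[allele_id]
        lookup.setdefault(seq, allele_id)
        lookup.setdefault(reverse_complement(seq), allele_id)
    return lookup


def classify_reads(records: Iterable[DemuxRecord], panel: ReferencePanel,
                   locus: str) -> list[CorrectReadStats]:
    """Score assigned reads against the reference panel, one stats row per
    experimental unit.

    A read is correct iff its trimmed insert equals a reference allele of its
    individual exactly (length included; the reverse-complement also counts,
    as a safety net — orientation is already normalised at demux).  Raises
    ``KeyError`` naming the unit when an individual is missing from the panel.
    """
    per_unit_reads: dict[ExperimentalUnit, list[str]] = defaultdict(list)
    for rec in records:
        if rec.assigned:
            per_unit_reads[rec.unit].append(rec.trimmed_insert)
    out: list[CorrectReadStats] = []
    for unit in sorted(per_unit_reads):
        try:
            alleles = panel.alleles(unit.individual, locus)
        except KeyError:
            raise KeyError(
                f"individual {unit.individual!r} at locus {locus!r} missing "
                f"from reference panel (unit {unit})")
        lookup = _identity_lookup(alleles)
        counts: Counter = Counter()
        for insert in per_unit_reads[unit]:
            allele_id = lookup.get(insert)
            if allele_id is not None:
                counts[allele_id] += 1
        out.append(CorrectReadStats(unit, len(per_unit_reads[unit]),
                                    sum(counts.values()), dict(counts)))
    return out


_UNIT_FIELDS = ("system", "enzyme", "pcr_condition", "individual")


def pool_stats(stats: Iterable[CorrectReadStats],
               by: Sequence[str] = ("system", "enzyme")
               ) -> list[CorrectReadStats]:
    """Pool counts over units sharing the given key fields.

    Fields not in ``by`` are set to ``"pooled"`` in the output key; counts
    (total, correct, per-allele) are summed and p̂ recomputed from the pooled
    counts, so pooling is exactly additive.
    """
    by = tuple(by)
    unknown = set(by) - set(_UNIT_FIELDS)
    if unknown:
        raise ValueError(f"unknown unit fields: {sorted(unknown)}")
    grouped: dict[ExperimentalUnit, list[CorrectReadStats]] = defaultdict(list)
    for s in stats:
        key = ExperimentalUnit(*(getattr(s.unit, f) if f in by else "pooled"
                                 for f in _UNIT_FIELDS))
        grouped[key].append(s)
    out = []
    for key in sorted(grouped):
        members = grouped[key]
        allele_counts: Counter = Counter()
        for s in members:
            allele_counts.update(s.per_allele_counts)
        out.append(CorrectReadStats(
            key,
            sum(s.n_reads for s in members),
            sum(s.n_correct for s in members),
            dict(allele_counts),
        ))
    return out


def stats_frame(stats: Iterable[CorrectReadStats]) -> pd.DataFrame:
    """Tabulate stats as delimited-text-ready rows."""
    rows = []
    for s in stats:
        rows.append({
            "system": s.unit.system, "enzyme": s.unit.enzyme,
            "pcr_condition": s.unit.pcr_condition,
            "individual": s.unit.individual,
            "n_reads": s.n_reads, "n_correct": s.n_correct,
            "p_hat": s.p_hat, "included": s.included,
        })
    return pd.DataFrame(rows)


def stats_from_frame(df: pd.DataFrame) -> list[CorrectReadStats]:
    """Inverse of :func:`stats_frame` (per-allele detail is not round-tripped)."""
    out = []
    for row in df.itertuples(index=False):
        unit = ExperimentalUnit(str(row.system), str(row.enzyme),
                                str(row.pcr_condition), str(row.individual))
        n_correct = int(row.n_correct)
        out.append(CorrectReadStats(unit, int(row.n_reads), n_correct,
                                    {"_pooled": n_correct} if n_correct else {}))
    return out
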