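"""Tailed-amplicon read architecture, sequence input and MID demultiplexing.

Models the two-round "universal tailed amplicon" library design used on
454-style platforms: round-1 PCR uses locus-specific primers carrying an M13
tail; round-2 PCR adds the sequencing adaptor (ending in a 4 bp key) and a
sample-specific 10 bp multiplex identifier (MID).  A full-length read
therefore has the structure

    adaptor+key | MID | M13 tail | locus primer | insert |
    rc(locus primer) | rc(M13 tail) | rc(MID) | rc(adaptor)

in either orientation.  Demultiplexing requires the complete MID, complete
tail and complete primers (IUPAC-aware for primer degeneracy, literal for
MIDs and tails) at both ends, plus an insert length inside the design range;
anything less is rejected.  Rejects are data, not errors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IUPAC_CODES",
    "SYSTEM_LABELS",
    "AmpliconDesign",
    "ExperimentalUnit",
    "SampleSheet",
    "DemuxRecord",
    "DemuxSummary",
    "read_sequences",
    "write_fasta",
    "reverse_complement",
    "iupac_match",
    "demultiplex",
    "load_design",
    "save_design",
]

#: IUPAC nucleotide codes and the concrete bases each stands for.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Canonical genetic-system labels, by increasing complexity: a single
#: haplotype (e.g. mtDNA), a single-copy nuclear gene with up to two alleles,
#: and a multigene family with several alleles per individual.
SYSTEM_LABELS = ("simple", "two_allele", "multigene")

_IUPAC_SET = frozenset(IUPAC_CODES)


def _validate_dna(seq: str, what: str) -> str:
    s = seq.upper()
    bad = set(s) - _IUPAC_SET
    if bad:
        raise ValueError(f"{what} contains non-IUPAC characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (upper-cased).

    Raises ``ValueError`` on non-IUPAC characters.  Applying it twice
    returns the input.
    """
    s = _validate_dna(seq, "sequence")
    return str(Seq(s).reverse_complement())


def iupac_match(pattern: str, text: str) -> bool:
    """True if ``text`` base-matches ``pattern`` with IUPAC degeneracy
    honoured in the pattern (e.g. pattern Y matches C or T).  Lengths must
    be equal; text bases are taken literally."""
    if len(pattern) != len(text):
        return False
    for p, t in zip(pattern, text):
        if t not in IUPAC_CODES.get(p, ""):
            return False
    return True


@dataclass(frozen=True)
class AmpliconDesign:
    """Two-round tailed-primer architecture for one locus.

    Sequences may be given in any case (tails are conventionally written in
    lower case); they are stored upper-cased.  ``insert_length_range`` is the
    inclusive [min, max] insert size in bases, excluding primers.
    """

    locus_name: str
    forward_primer: str
    reverse_primer: str
    forward_tail: str
    reverse_tail: str
    adaptor_forward: str
    adaptor_reverse: str
    insert_length_range: tuple[int, int]
    mid_length: int = 10
    key_length: int = 4

    def __post_init__(self) -> None:
        if not self.locus_name:
            raise ValueError("locus_name must be non-empty")
        for name in ("forward_primer", "reverse_primer", "forward_tail",
                     "reverse_tail", "adaptor_forward", "adaptor_reverse"):
            value = getattr(self, name)
            if not value:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, _validate_dna(value, name))
        if self.mid_length <= 0:
            raise ValueError("mid_length must be positive")
        if self.key_length < 0:
            raise ValueError("key_length must be non-negative")
        lo, hi = self.insert_length_range
        if lo > hi:
            raise ValueError(f"insert_length_range min {lo} exceeds max {hi}")
        object.__setattr__(self, "insert_length_range", (int(lo), int(hi)))


@dataclass(frozen=True, order=True)
class ExperimentalUnit:
    """(genetic system, enzyme, PCR condition, individual): the key over
    which correct-read proportions are computed.  Canonical system labels
    are listed in :data:`SYSTEM_LABELS`; pooled keys may use ``"pooled"``."""

    system: str
    enzyme: str
    pcr_condition: str
    individual: str

    def __post_init__(self) -> None:
        for name in ("system", "enzyme", "pcr_condition", "individual"):
            if not getattr(self, name):
                raise ValueError(f"ExperimentalUnit.{name} must be non-empty")


@dataclass
class SampleSheet:
    """Mapping from (MID, locus) to experimental unit.

    Within one locus a MID identifies exactly one unit; the same MID may be
    reused across loci (the locus primer disambiguates).
    """

    entries: dict[tuple[str, str], ExperimentalUnit] = field(default_factory=dict)

    def add(self, mid: str, locus: str, unit: ExperimentalUnit) -> None:
        mid = _validate_dna(mid, "MID")
        key = (mid, locus)
        if key in self.entries and self.entries[key] != unit:
            raise ValueError(f"MID {mid} maps to two units for locus {locus}")
        self.entries[key] = unit

    def for_locus(self, locus: str) -> dict[str, ExperimentalUnit]:
        return {mid: u for (mid, loc), u in self.entries.items() if loc == locus}

    def validate_against(self, design: AmpliconDesign) -> None:
        for mid in self.for_locus(design.locus_name):
            if len(mid) != design.mid_length:
                raise ValueError(
                    f"MID {mid} has length {len(mid)}, design expects "
                    f"{design.mid_length}"
                )

    @classmethod
    def from_table(cls, path: str | Path) -> "SampleSheet":
        """Load from delimited text with columns
        mid, locus, system, enzyme, pcr_condition, individual."""
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        required = {"mid", "locus", "system", "enzyme", "pcr_condition", "individual"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        sheet = cls()
        for row in df.itertuples(index=False):
            unit = ExperimentalUnit(row.system, row.enzyme,
                                    row.pcr_condition, row.individual)
            sheet.add(row.mid, row.locus, unit)
        return sheet

    def to_table(self, path: str | Path) -> None:
        rows = [
            {"mid": mid, "locus": locus, "system": u.system, "enzyme": u.enzyme,
             "pcr_condition": u.pcr_condition, "individual": u.individual}
            for (mid, locus), u in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


#: reject_reason values, in reporting precedence order (an assigned read has
#: reason "none").
REJECT_REASONS = ("none", "ambiguous_mid", "length_out_of_range",
                  "incomplete_primer", "no_mid")


@dataclass(frozen=True)
class DemuxRecord:
    """Outcome of demultiplexing one read.  ``unit`` and ``trimmed_insert``
    are present exactly when ``reject_reason == "none"``."""

    read_id: str
    unit: ExperimentalUnit | None
    orientation: str  # "forward", "reverse" or "unassigned"
    trimmed_insert: str | None
    reject_reason: str

    @property
    def assigned(self) -> bool:
        return self.reject_reason == "none"


@dataclass
class DemuxSummary:
    counts: Counter

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_assigned(self) -> int:
        return self.counts.get("none", 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": r, "n_reads": self.counts.get(r, 0)}
                for r in REJECT_REASONS]
        return pd.DataFrame(rows)


def read_sequences(path: str | Path, format: str = "fasta"
                   ) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA or FASTQ, in file order.

    Sequences are upper-cased; FASTQ qualities are discarded.  A record with
    non-IUPAC characters raises ``ValueError`` naming its index.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[tuple[str, str]] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            seq = str(rec.seq).upper()
            bad = set(seq) - _IUPAC_SET
            if bad:
                raise ValueError(
                    f"record {i} ({rec.id}) contains non-IUPAC characters: "
                    f"{sorted(bad)}"
                )
            out.append((rec.id, seq))
    except ValueError:
        raise
    except Exception as exc:  # malformed record mid-file
        raise ValueError(f"parse error in {path} near record {len(out)}: {exc}")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _find_structure(seq: str, design: AmpliconDesign,
                    mids: Mapping[str, ExperimentalUnit]):
    """Locate MID+tail+primer ... rc(primer)+rc(tail)+rc(MID) in one
    orientation.  Returns (status, mid, insert); status is "assigned",
    "ambiguous_mid", "incomplete_primer" or "no_mid"."""
    fp, rp = design.forward_primer, design.reverse_primer
    hits: list[tuple[str, str]] = []
    saw_mid = False
    for mid in mids:
        probe = mid + design.forward_tail
        start = seq.find(probe)
        while start >= 0:
            saw_mid = True
            p_start = start + len(probe)
            p_end = p_start + len(fp)
            if iupac_match(fp, seq[p_start:p_end]):
                # reverse-end structure: rc(reverse_primer)+rc(tail)+rc(mid)
                rev_probe = reverse_complement(mid + design.reverse_tail)
                j = seq.rfind(rev_probe)
                ins_end = j - len(rp)
                if j >= 0 and ins_end >= p_end and iupac_match(
                        reverse_complement(rp), seq[ins_end:j]):
                    hits.append((mid, seq[p_end:ins_end]))
                    break
            start = seq.find(probe, start + 1)
    if len({mid for mid, _ in hits}) > 1:
        return "ambiguous_mid", None, None
    if hits:
        return "assigned", hits[0][0], hits[0][1]
    return ("incomplete_primer" if saw_mid else "no_mid"), None, None


def demultiplex(reads: Iterable[tuple[str, str]], design: AmpliconDesign,
                sheet: SampleSheet
                ) -> tuple[list[DemuxRecord], DemuxSummary]:
    """Assign reads to experimental units for one locus.

    A read is assigned iff, in either orientation, it contains in order a
    complete MID from the sheet, the complete tail and the complete
    locus-specific primer at both ends (exact matching, IUPAC-aware for
    primer degeneracy only) and the trimmed insert length lies within the
    design range.  Every input read yields exactly one :class:`DemuxRecord`.
    """
    sheet.validate_against(design)
    mids = sheet.for_locus(design.locus_name)
    lo, hi = design.insert_length_range
    records: list[DemuxRecord] = []
    counts: Counter = Counter()
    for read_id, raw in reads:
        seq = raw.upper()
        best = "no_mid"
        result: DemuxRecord | None = None
        for orientation, oriented in (("forward", seq),
                                      ("reverse", reverse_complement(seq))):
            status, mid, insert = _find_structure(oriented, design, mids)
            if status == "assigned":
                if lo <= len(insert) <= hi:
                    result = DemuxRecord(read_id, mids[mid], orientation,
                                         insert, "none")
                    break
                status = "length_out_of_range"
            if REJECT_REASONS.index(status) < REJECT_REASONS.index(best):
                best = status
        if result is None:
            result = DemuxRecord(read_id, None, "unassigned", None, best)
        records.append(result)
        counts[result.reject_reason] += 1
    return records, DemuxSummary(counts)


def load_design(path: str | Path) -> AmpliconDesign:
    """Load an :class:`AmpliconDesign` from a YAML mapping of its fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["insert_length_range"] = tuple(data["insert_length_range"])
    return AmpliconDesign(**data)


def save_design(design: AmpliconDesign, path: str | Path) -> None:
    data = {
        "locus_name": design.locus_name,
        "forward_primer": design.forward_primer,
        "reverse_primer": design.reverse_primer,
        "forward_tail": design.forward_tail,
        "reverse_tail": design.reverse_tail,
        "adaptor_forward": design.adaptor_forward,
        "adaptor_reverse": design.adaptor_reverse,
        "insert_length_range": list(design.insert_length_range),
        "mid_length": design.mid_length,
        "key_length": design.key_length,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
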