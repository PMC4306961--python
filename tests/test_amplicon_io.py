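"""Sequence input, reverse complement and MID demultiplexing."""

import pytest
from hypothesis import given, settings, strategies as st

from ampcov.amplicon_io import (
    AmpliconDesign,
    SampleSheet,
    demultiplex,
    iupac_match,
    read_sequences,
    reverse_complement,
)
from conftest import build_read

DNA = st.text(alphabet="ACGT", min_size=1, max_size=60)
IUPAC = st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=40)


class TestReadSequences:
    def test_fasta_in_file_order(self, tmp_path):
        path = tmp_path / "r.fasta"
        path.write_text(">r1\nacgt\n>r2\nTTAA\n>r3\nGG\nGG\n")
        records = read_sequences(path, "fasta")
        assert records == [("r1", "ACGT"), ("r2", "TTAA"), ("r3", "GGGG")]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_sequences(path, "fasta") == []

    def test_fastq_qualities_discarded(self, tmp_path):
        path = tmp_path / "r.fastq"
        path.write_text("@r1\nACGT\n+\nIIII\n")
        assert read_sequences(path, "fastq") == [("r1", "ACGT")]

    def test_non_iupac_character_names_record(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">ok\nACGT\n>bad\nACXT\n")
        with pytest.raises(ValueError, match="record 1"):
            read_sequences(path, "fasta")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sequences(tmp_path / "nope.fasta", "fasta")


class TestReverseComplement:
    @pytest.mark.parametrize("seq, expected", [
        ("ACGT", "ACGT"),      # palindrome
        ("GAATTC", "GAATTC"),  # EcoRI palindrome
        ("AAC", "GTT"),
        ("ayk", "MRT"),        # IUPAC codes, case-insensitive
    ])
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGX")

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seq=IUPAC)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq.upper()


def test_iupac_match_degeneracy():
    assert iupac_match("AYKN", "ACGT")
    assert iupac_match("AYKN", "ATTA")
    assert not iupac_match("AYKN", "AAGT")  # Y is C/T only
    assert not iupac_match("ACG", "ACGT")   # length mismatch


def test_design_validation():
    with pytest.raises(ValueError, match="insert_length_range"):
        AmpliconDesign("x", "ACGT", "ACGT", "A", "A", "A", "A", (30, 20))
    with pytest.raises(ValueError, match="non-IUPAC"):
        AmpliconDesign("x", "ACXT", "ACGT", "A", "A", "A", "A", (1, 2))
    with pytest.raises(ValueError, match="mid_length"):
        AmpliconDesign("x", "ACGT", "ACGT", "A", "A", "A", "A", (1, 2),
                       mid_length=0)


def test_sample_sheet_rejects_conflicting_mid(toy_design, toy_unit):
    sheet = SampleSheet()
    sheet.add("AACCGG", "toy", toy_unit)
    other = type(toy_unit)("simple", "EnzB", "standard", "ind2")
    with pytest.raises(ValueError, match="two units"):
        sheet.add("AACCGG", "toy", other)


INSERT = "ACAGTGACCTAGGACTGACAGATT"  # 24 bp, inside the toy range


class TestDemultiplex:
    def test_constructed_read_is_assigned_and_trimmed(self, toy_design,
                                                      toy_sheet, toy_unit):
        read = build_read(toy_design, "AACCGG", INSERT)
        records, summary = demultiplex([("r1", read)], toy_design, toy_sheet)
        assert summary.n_assigned == 1
        rec = records[0]
        assert rec.unit == toy_unit
        assert rec.trimmed_insert == INSERT
        assert rec.orientation == "forward"

    def test_reverse_orientation_read_is_assigned(self, toy_design, toy_sheet,
                                                  toy_unit):
        read = reverse_complement(build_read(toy_design, "AACCGG", INSERT))
        records, _ = demultiplex([("r1", read)], toy_design, toy_sheet)
        assert records[0].unit == toy_unit
        assert records[0].trimmed_insert == INSERT
        assert records[0].orientation == "reverse"

    def test_degenerate_primer_positions_accept_either_base(self, toy_design,
                                                            toy_sheet):
        # reverse primer TTGGCCAART: R matches A or G, nothing else
        for base, ok in (("A", True), ("G", True), ("C", False)):
            realisation = toy_design.reverse_primer.replace("R", base)
            read = build_read(toy_design, "AACCGG", INSERT,
                              rev_primer_realisation=realisation)
            _, summary = demultiplex([("r", read)], toy_design, toy_sheet)
            assert (summary.n_assigned == 1) is ok

    def test_deleted_mid_base_rejected_no_mid(self, toy_design, toy_sheet):
        read = build_read(toy_design, "AACCGG", INSERT)
        broken = read.replace("AACCGG" + "GTTTTCCC", "AACGG" + "GTTTTCCC", 1)
        records, _ = demultiplex([("r1", broken)], toy_design, toy_sheet)
        assert records[0].reject_reason == "no_mid"
        assert records[0].unit is None and records[0].trimmed_insert is None

    def test_truncated_primer_rejected(self, toy_design, toy_sheet):
        prefix = (toy_design.adaptor_forward + "AACCGG"
                  + toy_design.forward_tail + toy_design.forward_primer[:-2])
        records, _ = demultiplex([("r1", prefix + INSERT)], toy_design,
                                 toy_sheet)
        assert records[0].reject_reason == "incomplete_primer"

    def test_insert_below_range_rejected(self, toy_design, toy_sheet):
        short = INSERT[:toy_design.insert_length_range[0] - 1]
        read = build_read(toy_design, "AACCGG", short)
        records, _ = demultiplex([("r1", read)], toy_design, toy_sheet)
        assert records[0].reject_reason == "length_out_of_range"

    def test_ambiguous_mid_rejected(self, toy_design, toy_sheet):
        # a concatemer carrying complete structures for two different MIDs
        read = (build_read(toy_design, "AACCGG", INSERT)
                + build_read(toy_design, "TTGGCA", INSERT))
        records, _ = demultiplex([("r1", read)], toy_design, toy_sheet)
        assert records[0].reject_reason == "ambiguous_mid"

    def test_partition_invariant(self, toy_design, toy_sheet):
        reads = [
            ("a", build_read(toy_design, "AACCGG", INSERT)),
            ("b", build_read(toy_design, "TTGGCA", INSERT)),
            ("c", build_read(toy_design, "AACCGG", INSERT[:10])),
            ("d", "ACGT" * 30),
        ]
        records, summary = demultiplex(reads, toy_design, toy_sheet)
        assert len(records) == len(reads)
        assert summary.n_total == len(reads)
        assert sum(summary.counts.values()) == len(reads)

    def test_orientation_symmetry(self, toy_design, toy_sheet):
        reads = [
            ("a", build_read(toy_design, "AACCGG", INSERT)),
            ("b", build_read(toy_design, "TTGGCA", INSERT)),
            ("c", build_read(toy_design, "AACCGG", INSERT[:10])),
            ("d", "ACGT" * 30),
        ]
        flipped = [(rid, reverse_complement(seq)) for rid, seq in reads]
        _, fwd = demultiplex(reads, toy_design, toy_sheet)
        _, rev = demultiplex(flipped, toy_design, toy_sheet)
        assert fwd.counts == rev.counts

    def test_mid_length_mismatch_raises(self, toy_design, toy_unit):
        sheet = SampleSheet()
        sheet.add("AAAA", toy_design.locus_name, toy_unit)
        with pytest.raises(ValueError, match="length"):
            demultiplex([], toy_design, sheet)


def test_zero_error_simulated_reads_fully_assigned():
    """Round trip: the generator's reads demultiplex 100% back to their
    generating unit when all error knobs are off."""
    from ampcov.amplicon_io import ExperimentalUnit
    from ampcov.simulate import EnzymeErrorProfile, default_designs, \
        simulate_unit

    design = default_designs()["simple"]
    unit = ExperimentalUnit("simple", "EnzA", "standard", "ind1")
    allele = "ACGT" * 42 + "AC"  # 170 bp, in range
    profile = EnzymeErrorProfile("EnzA", target_p_correct=1.0)
    reads, _ = simulate_unit(design, {"a1": allele}, profile, 50,
                             "ACGTACGTAC", seed=11, unit=unit)
    sheet = SampleSheet()
    sheet.add("ACGTACGTAC", design.locus_name, unit)
    records, summary = demultiplex(reads, design, sheet)
    assert summary.n_assigned == 50
    assert all(r.unit == unit and r.trimmed_insert == allele for r in records)
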