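import pytest

from ampcov.amplicon_io import AmpliconDesign, ExperimentalUnit, SampleSheet
from ampcov.amplicon_io import reverse_complement as rc


@pytest.fixture
def toy_design() -> AmpliconDesign:
    """Small hand-auditable tailed-amplicon design (short tails/primers so
    constructed reads stay readable)."""
    return AmpliconDesign(
        locus_name="toy",
        forward_primer="ACGTACGTAC",
        reverse_primer="TTGGCCAART",  # degenerate R exercises IUPAC matching
        forward_tail="gttttccc",
        reverse_tail="aacagcta",
        adaptor_forward="CGTATCGCCTCAG",
        adaptor_reverse="CTATGCGCTCAG",
        insert_length_range=(20, 30),
        mid_length=6,
        key_length=4,
    )


@pytest.fixture
def toy_unit() -> ExperimentalUnit:
    return ExperimentalUnit("simple", "EnzA", "standard", "ind1")


@pytest.fixture
def toy_sheet(toy_design, toy_unit) -> SampleSheet:
    sheet = SampleSheet()
    sheet.add("AACCGG", toy_design.locus_name, toy_unit)
    sheet.add("TTGGCA", toy_design.locus_name,
              ExperimentalUnit("simple", "EnzB", "standard", "ind2"))
    return sheet


def build_read(design: AmpliconDesign, mid: str, insert: str,
               rev_primer_realisation: str | None = None) -> str:
    """Concatenate the full two-round amplicon structure around an insert."""
    rev_primer = rev_primer_realisation or design.reverse_primer.replace("R", "A")
    return (design.adaptor_forward + mid + design.forward_tail
            + design.forward_primer + insert
            + rc(rev_primer) + rc(design.reverse_tail)
            + rc(mid) + rc(design.adaptor_reverse))
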