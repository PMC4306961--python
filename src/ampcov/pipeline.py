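"""Convenience glue: run demultiplexing and classification across the loci
of a multi-system experiment in one call."""

from __future__ import annotations

from typing import Iterable, Mapping

from .amplicon_io import AmpliconDesign, DemuxRecord, DemuxSummary, \
    SampleSheet, demultiplex
from .classify import CorrectReadStats, ReferencePanel, classify_reads

__all__ = ["run_pipeline"]


def run_pipeline(reads: Iterable[tuple[str, str]],
                 designs: Mapping[str, AmpliconDesign],
                 sheet: SampleSheet,
                 panel: ReferencePanel,
                 ) -> tuple[list[CorrectReadStats],
                            dict[str, list[DemuxRecord]],
                            dict[str, DemuxSummary]]:
    """Demultiplex a mixed read pool against every design, then classify.

    Each read can only carry one locus's primer structure, so running the
    demultiplexer per design partitions the pool.  Returns the combined
    per-unit statistics plus the per-locus demux records and summaries.
    """
    reads = list(reads)
    stats: list[CorrectReadStats] = []
    records: dict[str, list[DemuxRecord]] = {}
    summaries: dict[str, DemuxSummary] = {}
    for design in designs.values():
        recs, summary = demultiplex(reads, design, sheet)
        records[design.locus_name] = recs
        summaries[design.locus_name] = summary
        stats.extend(classify_reads(recs, panel, design.locus_name))
    return stats, records, summaries
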