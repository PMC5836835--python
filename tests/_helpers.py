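"""Shared constructors for test fixtures."""

from terius import TranscriptModel, TranscriptSet
from terius.annotation import GenomicInterval


def make_tx(tid, exon_coords, strand="+", chrom="chr1", gene=None, cds=None):
    """Build a TranscriptModel from (start, end) tuples."""
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    cds_ivs = [GenomicInterval(chrom, s, e, strand) for s, e in cds] if cds else None
    return TranscriptModel(tid, gene or tid, exons, cds=cds_ivs)


def make_set(*transcripts, build="testbuild"):
    ts = TranscriptSet(genome_build=build)
    for tx in transcripts:
        ts.add(tx)
    return ts


def reads_at_transcript_positions(tx, tpositions):
    """AlignedReads whose 5' ends sit at the given spliced coordinates of tx."""
    from terius.signals import AlignedRead

    return [
        AlignedRead(tx.chrom, tx.to_genomic_coord(int(t)), tx.strand, 30)
        for t in tpositions
    ]
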