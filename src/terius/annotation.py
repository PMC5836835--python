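"""Transcript annotation I/O and training-set construction filters.

Reads stranded transcript models from GTF (Ensembl dialect) or BED12,
derives CDS and 3'UTR sub-regions, and implements the isoform-selection
and same-strand overlap filters used to build classifier training sets:
longest-CDS isoforms for the coding reference, overlap-free longest-3'UTR
isoforms for the 3'UTR-fragment negatives, and exon-overlap removal for
the lncRNA positives.

All coordinates are 0-based half-open internally (BED native; GTF is
converted on read).
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("terius")

STRANDS = ("+", "-")


class AnnotationParseError(ValueError):
    """Raised on a malformed annotation line; message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


def _interval_list_length(ivs: list[GenomicInterval]) -> int:
    return sum(len(iv) for iv in ivs)


@dataclass
class TranscriptModel:
    """A stranded multi-exon transcript with optional CDS and 3'UTR sub-regions.

    Exons are kept sorted by genomic start and must share one chrom/strand.
    Transcript coordinates run 5'→3': position 0 is the leftmost exonic base
    on the plus strand and the rightmost exonic base on the minus strand.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] | None = None
    utr3: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons span multiple chrom/strand")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        # cumulative exon lengths for coordinate mapping
        self._starts = [e.start for e in self.exons]
        self._cum = np.concatenate([[0], np.cumsum([len(e) for e in self.exons])])

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length(self) -> int:
        return int(self._cum[-1])

    @property
    def cds_spliced_length(self) -> int:
        return _interval_list_length(self.cds) if self.cds else 0

    @property
    def utr3_spliced_length(self) -> int:
        return _interval_list_length(self.utr3) if self.utr3 else 0

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    def to_transcript_coord(self, genomic_pos: int) -> int | None:
        """Map a genomic base to its spliced transcript coordinate (None if intronic)."""
        i = bisect_right(self._starts, genomic_pos) - 1
        if i < 0 or genomic_pos >= self.exons[i].end:
            return None
        plus_offset = int(self._cum[i]) + (genomic_pos - self.exons[i].start)
        if self.strand == "+":
            return plus_offset
        return self.spliced_length - 1 - plus_offset

    def to_genomic_coord(self, t: int) -> int:
        """Inverse of :meth:`to_transcript_coord` for 0 <= t < spliced_length."""
        if not (0 <= t < self.spliced_length):
            raise IndexError(f"transcript coordinate {t} out of range")
        plus_offset = t if self.strand == "+" else self.spliced_length - 1 - t
        i = int(np.searchsorted(self._cum, plus_offset, side="right")) - 1
        return self.exons[i].start + (plus_offset - int(self._cum[i]))

    def spliced_slice(self, t_start: int, t_end: int) -> list[GenomicInterval]:
        """Genomic intervals covering transcript coordinates [t_start, t_end)."""
        if not (0 <= t_start < t_end <= self.spliced_length):
            raise IndexError(f"slice [{t_start}, {t_end}) out of range")
        # convert to plus-strand spliced offsets
        if self.strand == "+":
            lo, hi = t_start, t_end
        else:
            lo, hi = self.spliced_length - t_end, self.spliced_length - t_start
        out: list[GenomicInterval] = []
        for i, exon in enumerate(self.exons):
            a = max(lo, int(self._cum[i]))
            b = min(hi, int(self._cum[i + 1]))
            if a < b:
                g0 = exon.start + (a - int(self._cum[i]))
                out.append(GenomicInterval(self.chrom, g0, g0 + (b - a), self.strand))
        return out


@dataclass
class TranscriptSet:
    """A collection of transcripts with unique ids, tagged by genome build."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    genome_build: str = "unknown"

    def add(self, tx: TranscriptModel) -> None:
        if tx.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript_id {tx.transcript_id}")
        self.transcripts[tx.transcript_id] = tx

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts


# ---------------------------------------------------------------------------
# 3'UTR derivation
# ---------------------------------------------------------------------------

def derive_utr3(exons: list[GenomicInterval], cds: list[GenomicInterval]) -> list[GenomicInterval]:
    """Exonic region strictly 3' of the CDS (stop codon excluded from the UTR).

    The CDS interval list is taken to end at the stop codon's last base;
    everything exonic downstream of it, in transcript orientation, is 3'UTR.
    """
    if not cds:
        return []
    strand = exons[0].strand
    chrom = exons[0].chrom
    if strand == "+":
        cds_end = max(c.end for c in cds)
        pieces = [
            GenomicInterval(chrom, max(e.start, cds_end), e.end, strand)
            for e in exons
            if e.end > cds_end
        ]
    else:
        cds_end = min(c.start for c in cds)
        pieces = [
            GenomicInterval(chrom, e.start, min(e.end, cds_end), strand)
            for e in exons
            if e.start < cds_end
        ]
    return pieces


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(s: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(s))


def read_annotation(path: str, format: str = "auto") -> TranscriptSet:
    """Read a transcript annotation from GTF or BED12 into a TranscriptSet.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Records without strand information are rejected and counted; the count
    is logged. Malformed lines raise :class:`AnnotationParseError` naming
    the line number.
    """
    if format == "auto":
        format = "gtf" if str(path).endswith((".gtf", ".gff")) else "bed12"
    if format == "gtf":
        return _read_gtf(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gtf(path: str) -> TranscriptSet:
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    rejected_strandless = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(f"{path}:{lineno}: expected 9 GTF fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "CDS", "stop_codon"):
                continue
            try:
                start = int(start_s) - 1  # GTF is 1-based closed
                end = int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: bad coordinates") from exc
            if strand not in STRANDS:
                rejected_strandless += 1
                continue
            a = _parse_gtf_attributes(attrs)
            tid = a.get("transcript_id")
            if tid is None:
                raise AnnotationParseError(f"{path}:{lineno}: missing transcript_id attribute")
            gene_of.setdefault(tid, a.get("gene_id", tid))
            iv = GenomicInterval(chrom, start, end, strand)
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:  # CDS and stop_codon both count as coding sequence here
                cds.setdefault(tid, []).append(iv)
    if rejected_strandless:
        logger.info("read_annotation: rejected %d strandless records in %s", rejected_strandless, path)
    ts = TranscriptSet(genome_build="unknown")
    for tid, exon_list in sorted(exons.items()):
        cds_list = _merge_adjacent(sorted(cds.get(tid, []), key=lambda e: e.start))
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_of[tid],
            exons=exon_list,
            cds=cds_list or None,
        )
        tx.utr3 = derive_utr3(tx.exons, tx.cds) or None if tx.cds else None
        ts.add(tx)
    return ts


def _merge_adjacent(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge touching/overlapping sorted intervals (joins CDS with stop codon)."""
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.start <= out[-1].end:
            out[-1] = GenomicInterval(iv.chrom, out[-1].start, max(out[-1].end, iv.end), iv.strand)
        else:
            out.append(iv)
    return out


def _read_bed12(path: str) -> TranscriptSet:
    ts = TranscriptSet(genome_build="unknown")
    rejected_strandless = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationParseError(f"{path}:{lineno}: expected 12 BED fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                thick_start = int(fields[6])
                thick_end = int(fields[7])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except (ValueError, IndexError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: malformed BED12 record") from exc
            if strand not in STRANDS:
                rejected_strandless += 1
                continue
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationParseError(f"{path}:{lineno}: blockCount does not match block lists")
            # gene id may ride along as column 13; default to the record name
            gene_id = fields[12] if len(fields) > 12 and fields[12] else name
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            cds_list: list[GenomicInterval] | None = None
            if thick_end > thick_start:
                cds_list = [
                    GenomicInterval(chrom, max(e.start, thick_start), min(e.end, thick_end), strand)
                    for e in exons
                    if e.start < thick_end and e.end > thick_start
                ] or None
            tx = TranscriptModel(name, gene_id, exons, cds=cds_list)
            tx.utr3 = derive_utr3(tx.exons, tx.cds) or None if tx.cds else None
            ts.add(tx)
    if rejected_strandless:
        logger.info("read_annotation: rejected %d strandless records in %s", rejected_strandless, path)
    return ts


def write_bed12(ts: TranscriptSet, path: str) -> None:
    """Write a TranscriptSet as BED12 (gene_id carried in column 13)."""
    with open(path, "w") as fh:
        for tx in sorted(ts, key=lambda t: (t.chrom, t.exons[0].start, t.transcript_id)):
            start = tx.exons[0].start
            end = tx.exons[-1].end
            if tx.cds:
                thick_start = min(c.start for c in tx.cds)
                thick_end = max(c.end for c in tx.cds)
            else:
                thick_start = thick_end = start
            sizes = ",".join(str(len(e)) for e in tx.exons)
            offsets = ",".join(str(e.start - start) for e in tx.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        tx.chrom, start, end, tx.transcript_id, 0, tx.strand,
                        thick_start, thick_end, 0, len(tx.exons), sizes, offsets,
                        tx.gene_id,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Training-set selection filters
# ---------------------------------------------------------------------------

def select_longest_cds_isoform(ts: TranscriptSet) -> TranscriptSet:
    """Keep one isoform per gene: the one with the longest spliced CDS.

    Genes without any CDS-bearing isoform are dropped (count logged).
    Length ties break to the lexicographically smaller transcript_id.
    """
    by_gene: dict[str, TranscriptModel] = {}
    dropped_genes = set()
    for tx in ts:
        if tx.cds_spliced_length == 0:
            dropped_genes.add(tx.gene_id)
            continue
        cur = by_gene.get(tx.gene_id)
        if (
            cur is None
            or tx.cds_spliced_length > cur.cds_spliced_length
            or (tx.cds_spliced_length == cur.cds_spliced_length and tx.transcript_id < cur.transcript_id)
        ):
            by_gene[tx.gene_id] = tx
    dropped = dropped_genes - set(by_gene)
    if dropped:
        logger.info("select_longest_cds_isoform: %d genes without CDS excluded", len(dropped))
    out = TranscriptSet(genome_build=ts.genome_build)
    for tx in by_gene.values():
        out.add(tx)
    return out


def _interval_lists_overlap(a: list[GenomicInterval], b: list[GenomicInterval]) -> bool:
    for x in a:
        for y in b:
            if x.overlaps(y, same_strand=True):
                return True
    return False


def select_utr3_training_isoforms(ts: TranscriptSet) -> TranscriptSet:
    """Select one isoform per gene whose 3'UTR overlaps no CDS of any isoform.

    Among qualifying isoforms of a gene, the one with the longest spliced
    3'UTR wins (ties to the lexicographically smaller transcript_id). Genes
    with no qualifying isoform are dropped with a logged count.
    """
    all_cds = [(tx.transcript_id, tx.cds) for tx in ts if tx.cds]
    by_gene: dict[str, TranscriptModel] = {}
    genes_seen = set()
    for tx in ts:
        genes_seen.add(tx.gene_id)
        if not tx.utr3:
            continue
        clash = any(
            tid != tx.transcript_id and _interval_lists_overlap(tx.utr3, cds)
            for tid, cds in all_cds
        )
        if clash:
            continue
        cur = by_gene.get(tx.gene_id)
        if (
            cur is None
            or tx.utr3_spliced_length > cur.utr3_spliced_length
            or (tx.utr3_spliced_length == cur.utr3_spliced_length and tx.transcript_id < cur.transcript_id)
        ):
            by_gene[tx.gene_id] = tx
    n_dropped = len(genes_seen) - len(by_gene)
    if n_dropped:
        logger.info("select_utr3_training_isoforms: %d genes without qualifying 3'UTR dropped", n_dropped)
    out = TranscriptSet(genome_build=ts.genome_build)
    for tx in by_gene.values():
        out.add(tx)
    return out


def filter_lncrna_overlaps(lnc: TranscriptSet, others: TranscriptSet) -> TranscriptSet:
    """Remove lncRNAs sharing any exonic base, same strand, with other genes' exons.

    After the overlap filter, the longest spliced isoform per lncRNA gene is
    kept. Opposite-strand and purely intronic overlaps do not disqualify.
    """
    # per (chrom, strand) sorted exon arrays of the exclusion set
    other_exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for tx in others:
        for e in tx.exons:
            other_exons.setdefault((e.chrom, e.strand), []).append((e.start, e.end))
    starts: dict[tuple[str, str], np.ndarray] = {}
    ends: dict[tuple[str, str], np.ndarray] = {}
    for key, ivs in other_exons.items():
        ivs.sort()
        starts[key] = np.array([a for a, _ in ivs])
        ends[key] = np.maximum.accumulate(np.array([b for _, b in ivs]))

    def clean(tx: TranscriptModel) -> bool:
        key = (tx.chrom, tx.strand)
        if key not in starts:
            return True
        s, e = starts[key], ends[key]
        for exon in tx.exons:
            i = int(np.searchsorted(s, exon.end, side="left"))
            if i > 0 and e[i - 1] > exon.start:
                return False
        return True

    by_gene: dict[str, TranscriptModel] = {}
    for tx in lnc:
        if not clean(tx):
            continue
        cur = by_gene.get(tx.gene_id)
        if (
            cur is None
            or tx.spliced_length > cur.spliced_length
            or (tx.spliced_length == cur.spliced_length and tx.transcript_id < cur.transcript_id)
        ):
            by_gene[tx.gene_id] = tx
    out = TranscriptSet(genome_build=lnc.genome_build)
    for tx in by_gene.values():
        out.add(tx)
    return out
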