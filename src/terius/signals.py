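"""Read-derived signals: sub-codon counts, RPM expression, CLIP expansion.

Every statistic here is anchored on the 5' end of a read: the base that
determines both a read's sub-codon position within a transcript's reading
frame and its membership in a region when counting expression. Ribosome
footprint 5' ends carry the trinucleotide phasing of elongating ribosomes,
which is the raw material of the periodicity score; RNA-seq 5' ends give
expression (RPM); CLIP BED records are expanded into reads in proportion
to their signal intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pysam

from .annotation import GenomicInterval, TranscriptModel

logger = logging.getLogger("terius")

_SUBCODON = 3


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to its 5'-end anchor.

    ``five_prime_pos`` is genomic and 0-based; on the minus strand it is the
    alignment's highest coordinate.
    """

    chrom: str
    five_prime_pos: int
    strand: str
    length: int = 30

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0:
            raise ValueError("five_prime_pos must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


class ReadIndex:
    """5'-end positions indexed by (chrom, strand) for fast region counting."""

    def __init__(self, reads: Iterable[AlignedRead]):
        buckets: dict[tuple[str, str], list[int]] = {}
        n = 0
        for r in reads:
            buckets.setdefault((r.chrom, r.strand), []).append(r.five_prime_pos)
            n += 1
        self.positions = {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in buckets.items()}
        self.n_reads = n

    def in_interval(self, iv: GenomicInterval) -> np.ndarray:
        """Sorted 5'-end positions falling inside iv on its strand."""
        pos = self.positions.get((iv.chrom, iv.strand))
        if pos is None:
            return np.empty(0, dtype=np.int64)
        lo, hi = np.searchsorted(pos, [iv.start, iv.end])
        return pos[lo:hi]

    def count_in(self, ivs: Iterable[GenomicInterval]) -> int:
        return int(sum(len(self.in_interval(iv)) for iv in ivs))


def _as_index(reads) -> ReadIndex:
    return reads if isinstance(reads, ReadIndex) else ReadIndex(reads)


@dataclass
class SubcodonSignal:
    """Signal over the three sub-codon positions under one frame choice."""

    counts: np.ndarray  # shape (3,)
    frame: int = 0
    kind: str = "raw"  # raw | random | normalized

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (_SUBCODON,):
            raise ValueError("counts must be a length-3 vector")
        if np.any(self.counts < 0):
            raise ValueError("sub-codon counts must be non-negative")
        if self.kind == "normalized" and self.total > 0 and abs(self.total - 1.0) > 1e-9:
            raise ValueError("normalized signal must sum to 1")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class ExpressionLevel:
    """Region expression as raw 5'-end count and reads-per-million."""

    raw_count: float
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.raw_count < 0:
            raise ValueError("raw_count must be non-negative")

    @property
    def rpm(self) -> float:
        return self.raw_count * 1e6 / self.library_size


# ---------------------------------------------------------------------------
# Counting operations
# ---------------------------------------------------------------------------

def transcript_positions(reads, tx: TranscriptModel) -> np.ndarray:
    """Spliced transcript coordinates of every exonic same-strand 5' end."""
    idx = _as_index(reads)
    tpos: list[int] = []
    for exon in tx.exons:
        for g in idx.in_interval(exon):
            t = tx.to_transcript_coord(int(g))
            if t is not None:
                tpos.append(t)
    return np.asarray(tpos, dtype=np.int64)


def count_subcodon(
    reads,
    tx: TranscriptModel,
    frame: int = 0,
    collapse: bool = False,
) -> SubcodonSignal:
    """Count read 5' ends by sub-codon position under ``frame``.

    A read whose 5' end maps to spliced transcript coordinate ``t``
    contributes to position ``(t - frame) mod 3``. With ``collapse`` on,
    reads sharing a 5'-end transcript position count once — the dedup used
    for ribosome footprints before periodicity scoring. Intronic and
    opposite-strand reads are skipped.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    tpos = transcript_positions(reads, tx)
    if collapse:
        tpos = np.unique(tpos)
    sub = (tpos - frame) % _SUBCODON
    counts = np.bincount(sub, minlength=_SUBCODON).astype(float)
    return SubcodonSignal(counts, frame=frame, kind="raw")


def shift_frame(signal: SubcodonSignal, frame: int) -> SubcodonSignal:
    """Re-index a frame-0 raw signal to another frame (cyclic shift)."""
    counts = np.roll(signal.counts, -frame)
    return SubcodonSignal(counts, frame=frame, kind=signal.kind)


def compute_rpm(reads, region: list[GenomicInterval], library_size: int) -> ExpressionLevel:
    """Count 5' ends inside a region (same strand) and normalize per million."""
    if not region:
        raise ValueError("empty region")
    idx = _as_index(reads)
    raw = idx.count_in(region)
    return ExpressionLevel(raw_count=float(raw), library_size=library_size)


# ---------------------------------------------------------------------------
# SAM / BAM input
# ---------------------------------------------------------------------------

def read_alignments(path: str) -> tuple[ReadIndex, int]:
    """Load primary mapped alignments from SAM/BAM as a ReadIndex.

    Returns (index, library_size) where library_size counts primary mapped
    alignments — the RPM denominator.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, mode) as fh:
        for a in fh.fetch(until_eof=True):
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.is_reverse:
                reads.append(AlignedRead(a.reference_name, a.reference_end - 1, "-", a.query_length or 30))
            else:
                reads.append(AlignedRead(a.reference_name, a.reference_start, "+", a.query_length or 30))
    idx = ReadIndex(reads)
    return idx, idx.n_reads


# ---------------------------------------------------------------------------
# CLIP intensity BED expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClipRecord:
    chrom: str
    start: int
    end: int
    strand: str
    score: float


def read_clip_bed(path: str) -> list[ClipRecord]:
    """Read a BED6 of CLIP signal intensities (score column = intensity)."""
    out: list[ClipRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED fields")
            try:
                rec = ClipRecord(f[0], int(f[1]), int(f[2]), f[5], float(f[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed CLIP BED record") from exc
            out.append(rec)
    return out


def merge_clip_replicates(replicates: list[list[ClipRecord]]) -> list[ClipRecord]:
    """Merge replicate CLIP BED sets by per-interval mean intensity.

    Records are keyed by (chrom, start, end, strand); an interval absent
    from a replicate contributes 0 to its mean, so the merge is robust to
    replicate-specific peaks.
    """
    if not replicates:
        return []
    sums: dict[tuple[str, int, int, str], float] = {}
    for rep in replicates:
        for r in rep:
            key = (r.chrom, r.start, r.end, r.strand)
            sums[key] = sums.get(key, 0.0) + r.score
    n = len(replicates)
    return [
        ClipRecord(c, s, e, st, total / n)
        for (c, s, e, st), total in sorted(sums.items())
    ]


def expand_clip_bed(records: Iterable[ClipRecord], read_length: int = 30) -> Iterator[AlignedRead]:
    """Expand intensity-weighted CLIP records into reads.

    Each record emits round(score) identical reads anchored at the record's
    5' end (strand-aware). Fractional intensities (e.g. replicate means)
    round half-up; zero emits nothing; negative is an error.
    """
    for r in records:
        if r.score < 0:
            raise ValueError(f"negative CLIP intensity at {r.chrom}:{r.start}-{r.end}")
        n = int(np.floor(r.score + 0.5))
        if n == 0:
            continue
        anchor = r.start if r.strand == "+" else r.end - 1
        read = AlignedRead(r.chrom, anchor, r.strand, read_length)
        for _ in range(n):
            yield read
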