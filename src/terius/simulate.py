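"""Labeled synthetic fixtures with the signal structure both classifiers assume.

The generator lays single-exon transcripts head-to-tail on one synthetic
contig (alternating strands) and simulates three read sets:

* Ribo-seq — coding transcripts draw Poisson-distributed read counts whose
  5'-end sub-codon positions follow (frame_bias, (1-b)/2, (1-b)/2) in a
  per-transcript true frame; non-coding transcripts get uniform sub-codon
  positions at reduced depth, emulating scanning/background ribosomes.
* RNA-seq — uniform 5' ends over every transcript (expression).
* CLIP — Poisson counts scaled by a class enrichment factor, with an
  exactly assigned zero-signal fraction per class: UPF1-style association
  that is high on 3'UTR fragments and mostly absent on bona fide lncRNAs.

Transcript identity, true class label, and true frame are recorded, so
training, cross-validation and end-to-end classification are all testable
against known ground truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .annotation import GenomicInterval, TranscriptModel, TranscriptSet, write_bed12
from .signals import AlignedRead, ClipRecord

CONTIG = "chrS"
READ_LENGTH = 30
GAP = 200  # bp between simulated transcripts
MARGIN = 100  # bp before the first transcript (keeps minus-strand SAM starts valid)

LABEL_MRNA = "mRNA"
LABEL_LNCRNA = "lncRNA"
LABEL_UTR3 = "UTR3_fragment"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults encode moderately periodic translation (60% of footprint 5'
    ends in the true frame's first sub-codon position), ~100x read depth,
    5-fold CLIP enrichment on 3'UTR fragments, and a large zero-CLIP
    fraction among lncRNAs versus a small one among fragments.
    """

    n_coding: int = 150
    n_lncrna: int = 150
    n_utr_fragment: int = 150
    frame_bias: float = 0.6
    ribo_depth: float = 100.0  # mean Ribo-seq reads per coding transcript
    noncoding_ribo_frac: float = 0.5  # non-coding ribosome background vs ribo_depth
    rna_depth: float = 100.0
    clip_depth: float = 50.0
    clip_enrichment_utr: float = 5.0
    clip_enrichment_lnc: float = 1.0
    zero_clip_frac_lnc: float = 0.40
    zero_clip_frac_utr: float = 0.05
    length_range: tuple[int, int] = (300, 1500)
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.n_coding, self.n_lncrna, self.n_utr_fragment) < 0:
            raise ValueError("class sizes must be non-negative")
        if not (1 / 3 <= self.frame_bias <= 1.0):
            raise ValueError("frame_bias must be in [1/3, 1]")
        for name in ("zero_clip_frac_lnc", "zero_clip_frac_utr"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.ribo_depth, self.rna_depth, self.clip_depth) < 0:
            raise ValueError("depths must be non-negative")
        lo, hi = self.length_range
        if not (READ_LENGTH < lo <= hi):
            raise ValueError("length_range must satisfy 30 < lo <= hi")


@dataclass
class LabeledFixture:
    """A synthetic annotation plus read sets with known ground truth."""

    annotation: TranscriptSet
    true_labels: dict[str, str]
    true_frames: dict[str, int]  # coding transcripts only
    ribo_reads: list[AlignedRead] = field(default_factory=list)
    rna_reads: list[AlignedRead] = field(default_factory=list)
    clip_reads: list[AlignedRead] = field(default_factory=list)

    @property
    def contig_length(self) -> int:
        return max(tx.exons[-1].end for tx in self.annotation) + GAP


def _uniform_reads(rng, tx: TranscriptModel, n: int) -> list[AlignedRead]:
    tpos = rng.integers(0, tx.spliced_length, size=n)
    return [AlignedRead(tx.chrom, tx.to_genomic_coord(int(t)), tx.strand, READ_LENGTH) for t in tpos]


def _periodic_reads(rng, tx: TranscriptModel, n: int, frame: int, bias: float) -> list[AlignedRead]:
    """Reads whose 5'-end sub-codon position favors `frame` with prob `bias`."""
    offsets = rng.choice(3, size=n, p=[bias, (1 - bias) / 2, (1 - bias) / 2])
    n_codons = tx.spliced_length // 3 - 1
    codons = rng.integers(0, n_codons, size=n)
    out = []
    for c, off in zip(codons, offsets):
        t = int(frame + 3 * c + off)
        out.append(AlignedRead(tx.chrom, tx.to_genomic_coord(t), tx.strand, READ_LENGTH))
    return out


def simulate_fixture(cfg: SimulationConfig) -> LabeledFixture:
    """Generate the full labeled benchmark for one seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    annotation = TranscriptSet(genome_build="sim1")
    labels: dict[str, str] = {}
    frames: dict[str, int] = {}

    specs = (
        [(LABEL_MRNA, i) for i in range(cfg.n_coding)]
        + [(LABEL_LNCRNA, i) for i in range(cfg.n_lncrna)]
        + [(LABEL_UTR3, i) for i in range(cfg.n_utr_fragment)]
    )
    cursor = MARGIN
    for label, i in specs:
        tid = f"sim_{label}_{i:04d}"
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        strand = "+" if rng.integers(2) == 0 else "-"
        tx = TranscriptModel(tid, tid, [GenomicInterval(CONTIG, cursor, cursor + length, strand)])
        cursor += length + GAP
        if label == LABEL_MRNA:
            frame = int(rng.integers(3))
            frames[tid] = frame
            n_codons = length // 3 - 1
            tx.cds = tx.spliced_slice(frame, frame + 3 * n_codons)
        annotation.add(tx)
        labels[tid] = label

    fx = LabeledFixture(annotation, labels, frames)

    # Ribo-seq: periodic on coding, uniform background on non-coding
    for tx in annotation:
        label = labels[tx.transcript_id]
        if label == LABEL_MRNA:
            n = int(rng.poisson(cfg.ribo_depth))
            fx.ribo_reads.extend(
                _periodic_reads(rng, tx, n, frames[tx.transcript_id], cfg.frame_bias)
            )
        else:
            n = int(rng.poisson(cfg.ribo_depth * cfg.noncoding_ribo_frac))
            fx.ribo_reads.extend(_uniform_reads(rng, tx, n))

    # RNA-seq: uniform everywhere
    for tx in annotation:
        fx.rna_reads.extend(_uniform_reads(rng, tx, int(rng.poisson(cfg.rna_depth))))

    # CLIP: class-dependent enrichment with an exactly assigned zero fraction
    for label, enrich, zero_frac in (
        (LABEL_LNCRNA, cfg.clip_enrichment_lnc, cfg.zero_clip_frac_lnc),
        (LABEL_UTR3, cfg.clip_enrichment_utr, cfg.zero_clip_frac_utr),
        (LABEL_MRNA, cfg.clip_enrichment_lnc, 0.0),
    ):
        members = [tx for tx in annotation if labels[tx.transcript_id] == label]
        n_zero = int(round(zero_frac * len(members)))
        zero_ids = set(rng.permutation([tx.transcript_id for tx in members])[:n_zero])
        rate = cfg.clip_depth * enrich
        for tx in members:
            if tx.transcript_id in zero_ids or rate == 0:
                continue
            n = int(rng.poisson(rate))
            while n == 0:  # zero-truncated: zero association is assigned, not sampled
                n = int(rng.poisson(rate))
            fx.clip_reads.extend(_uniform_reads(rng, tx, n))
    return fx


# ---------------------------------------------------------------------------
# On-disk round trip (BED12 + SAM + intensity BED + labels TSV)
# ---------------------------------------------------------------------------

def _write_sam(reads: list[AlignedRead], path: Path, contig_length: int) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": CONTIG, "LN": int(contig_length)}]}
    ordered = sorted(reads, key=lambda r: (r.five_prime_pos, r.strand))
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, r in enumerate(ordered):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"r{i:07d}"
            a.query_sequence = "N" * r.length
            a.flag = 0 if r.strand == "+" else 16
            a.reference_id = 0
            a.reference_start = r.five_prime_pos if r.strand == "+" else r.five_prime_pos - r.length + 1
            a.mapping_quality = 255
            a.cigarstring = f"{r.length}M"
            fh.write(a)


def _write_clip_bed(reads: list[AlignedRead], path: Path) -> None:
    """Aggregate CLIP reads per 5' position into an intensity BED."""
    counts: dict[tuple[str, int, str], int] = {}
    for r in reads:
        key = (r.chrom, r.five_prime_pos, r.strand)
        counts[key] = counts.get(key, 0) + 1
    with open(path, "w") as fh:
        for (chrom, pos, strand), n in sorted(counts.items()):
            start = pos if strand == "+" else pos - READ_LENGTH + 1
            fh.write(f"{chrom}\t{start}\t{start + READ_LENGTH}\tclip\t{n}\t{strand}\n")


def write_fixture(fx: LabeledFixture, out_dir: str) -> dict[str, Path]:
    """Write annotation.bed, ribo.sam, rna.sam, clip.bed and labels.tsv.

    Outputs are plain text, deterministic for a fixed fixture, and re-read
    cleanly by the package's own annotation and signal readers.
    """
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": d / "annotation.bed",
        "ribo": d / "ribo.sam",
        "rna": d / "rna.sam",
        "clip": d / "clip.bed",
        "labels": d / "labels.tsv",
    }
    write_bed12(fx.annotation, str(paths["annotation"]))
    clen = fx.contig_length
    _write_sam(fx.ribo_reads, paths["ribo"], clen)
    _write_sam(fx.rna_reads, paths["rna"], clen)
    _write_clip_bed(fx.clip_reads, paths["clip"])
    with open(paths["labels"], "w") as fh:
        fh.write("transcript_id\ttrue_label\ttrue_frame\n")
        for tid in sorted(fx.true_labels):
            frame = fx.true_frames.get(tid, "")
            fh.write(f"{tid}\t{fx.true_labels[tid]}\t{frame}\n")
    return paths


def load_fixture(in_dir: str) -> LabeledFixture:
    """Re-read a written fixture through the package's own readers."""
    from .annotation import read_annotation
    from .signals import expand_clip_bed, read_alignments, read_clip_bed

    d = Path(in_dir)
    annotation = read_annotation(str(d / "annotation.bed"), "bed12")
    annotation.genome_build = "sim1"
    labels: dict[str, str] = {}
    frames: dict[str, int] = {}
    with open(d / "labels.tsv") as fh:
        next(fh)
        for line in fh:
            tid, label, frame = line.rstrip("\n").split("\t")
            labels[tid] = label
            if frame:
                frames[tid] = int(frame)
    ribo_idx, _ = read_alignments(str(d / "ribo.sam"))
    rna_idx, _ = read_alignments(str(d / "rna.sam"))
    clip_reads = list(expand_clip_bed(read_clip_bed(str(d / "clip.bed"))))

    def flatten(idx) -> list[AlignedRead]:
        out = []
        for (chrom, strand), pos in sorted(idx.positions.items()):
            out.extend(AlignedRead(chrom, int(p), strand, READ_LENGTH) for p in pos)
        return out

    return LabeledFixture(annotation, labels, frames,
                          flatten(ribo_idx), flatten(rna_idx), clip_reads)


def clip_reads_to_records(reads: list[AlignedRead]) -> list[ClipRecord]:
    """In-memory equivalent of the intensity BED written by write_fixture."""
    counts: dict[tuple[str, int, str], int] = {}
    for r in reads:
        key = (r.chrom, r.five_prime_pos, r.strand)
        counts[key] = counts.get(key, 0) + 1
    out = []
    for (chrom, pos, strand), n in sorted(counts.items()):
        start = pos if strand == "+" else pos - READ_LENGTH + 1
        out.append(ClipRecord(chrom, start, start + READ_LENGTH, strand, float(n)))
    return out
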