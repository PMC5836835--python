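"""Step 1 — ribosome periodicity scoring (WRE, MLRF, RPS).

Actively translated transcripts show trinucleotide phasing of ribosome
footprint 5' ends along the coding frame. Instead of enumerating ORFs, a
weighted relative entropy (WRE) compares a transcript's sub-codon signal
against the genome-wide sub-codon profile of annotated CDS regions:

    WRE(f) = sum_i obs_f(i) * RIBO_CDS(i) * ln(RIBO_CDS(i) / RNA_CDS(i))

The frame maximizing WRE is the most-likely reading frame (MLRF). Because
frame selection itself inflates position-0 signal, the MLRF signal is then
re-normalized against a random control (reads re-distributed uniformly
over the three positions) before the final WRE value theta is computed.
Theta feeds class-conditional densities into a Bayes posterior: the
ribosome periodicity score (RPS), the probability the transcript is
non-coding. Transcripts with a zero raw count in any sub-codon position at
the MLRF carry too little ribosome signal to score and are routed as low
ribosome transcripts (LRT).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np

from .annotation import TranscriptModel, TranscriptSet
from .model import DensityModel, bayes_posterior
from .signals import SubcodonSignal, count_subcodon, transcript_positions

logger = logging.getLogger("terius")

DEFAULT_RC_REPLICATES = 30
PSEUDOCOUNT = 0.5

ROUTE_MRNA = "mRNA"
ROUTE_NCRNA = "ncRNA"
ROUTE_LRT = "LRT"


class LowRibosomeSignal(ValueError):
    """Signal too sparse to normalize/score; transcript routes to LRT."""


@dataclass
class ReferenceProfile:
    """Genome-wide sub-codon distributions over CDS for Ribo-seq and RNA-seq.

    These are the WRE weights: RIBO_CDS(i) quantifies how strongly true
    translation favors sub-codon position i, RNA_CDS(i) is the matched
    background from RNA-seq.
    """

    ribo_cds: np.ndarray
    rna_cds: np.ndarray

    def __post_init__(self) -> None:
        self.ribo_cds = np.asarray(self.ribo_cds, dtype=float)
        self.rna_cds = np.asarray(self.rna_cds, dtype=float)
        for name, v in (("ribo_cds", self.ribo_cds), ("rna_cds", self.rna_cds)):
            if v.shape != (3,):
                raise ValueError(f"{name} must have 3 components")
            if np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")

    @property
    def weights(self) -> np.ndarray:
        """Per-position WRE weights RIBO_CDS(i) * ln(RIBO_CDS(i)/RNA_CDS(i))."""
        return self.ribo_cds * np.log(self.ribo_cds / self.rna_cds)


@dataclass
class RPSResult:
    """Per-transcript step-1 output."""

    transcript_id: str
    wre_by_frame: np.ndarray | None  # raw-proportion WRE for frames 0,1,2
    mlrf: int | None
    wre: float | None  # final theta: WRE of the control-normalized MLRF signal
    rps: float | None
    routing: str  # mRNA | ncRNA | LRT
    degenerate: bool = False  # posterior fell back to 0.5 (theta outside supports)


def cds_transcript_range(tx: TranscriptModel) -> tuple[int, int]:
    """Transcript-coordinate half-open range covered by the annotated CDS."""
    if not tx.cds:
        raise ValueError(f"{tx.transcript_id} has no CDS")
    if tx.strand == "+":
        g5 = min(c.start for c in tx.cds)
    else:
        g5 = max(c.end for c in tx.cds) - 1
    t0 = tx.to_transcript_coord(g5)
    if t0 is None:
        raise ValueError(f"{tx.transcript_id}: CDS start not exonic")
    return t0, t0 + tx.cds_spliced_length


def build_reference_profile(cds_transcripts: TranscriptSet, ribo, rna) -> ReferenceProfile:
    """Pool sub-codon counts over all annotated CDSs, anchored at each CDS start.

    Ribo-seq 5' ends are collapsed per transcript position (as for WRE
    input); RNA-seq is counted at raw depth. Each pooled triple is
    normalized to sum 1; any empty position is an error since the profile
    must be strictly positive to serve as WRE weights.
    """
    ribo_counts = np.zeros(3)
    rna_counts = np.zeros(3)
    for tx in cds_transcripts:
        if not tx.cds:
            continue
        t0, t1 = cds_transcript_range(tx)
        for counts, reads, collapse in ((ribo_counts, ribo, True), (rna_counts, rna, False)):
            tpos = transcript_positions(reads, tx)
            tpos = tpos[(tpos >= t0) & (tpos < t1)]
            if collapse:
                tpos = np.unique(tpos)
            counts += np.bincount((tpos - t0) % 3, minlength=3)
    if np.any(ribo_counts == 0) or np.any(rna_counts == 0):
        raise ValueError("reference profile has an empty sub-codon position")
    return ReferenceProfile(ribo_counts / ribo_counts.sum(), rna_counts / rna_counts.sum())


def wre(obs: SubcodonSignal | np.ndarray, prof: ReferenceProfile) -> float:
    """Weighted relative entropy of a normalized sub-codon signal."""
    v = obs.counts if isinstance(obs, SubcodonSignal) else np.asarray(obs, dtype=float)
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("wre expects a normalized signal summing to 1")
    return float(np.dot(v, prof.weights))


def random_control(total: float, rng_seed: int, replicates: int = DEFAULT_RC_REPLICATES) -> SubcodonSignal:
    """Uniform re-distribution of ``total`` reads over the 3 positions.

    Averaged over ``replicates`` seeded multinomial draws; each component
    has expectation total/3 and the components sum back to ``total``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if total < 0:
        raise ValueError("total must be non-negative")
    if total == 0:
        return SubcodonSignal(np.zeros(3), kind="random")
    rng = np.random.default_rng(rng_seed)
    n = int(round(total))
    draws = rng.multinomial(n, [1 / 3] * 3, size=replicates).astype(float)
    mean = draws.mean(axis=0)
    if n > 0 and total != n:  # preserve fractional totals exactly
        mean *= total / n
    return SubcodonSignal(mean, kind="random")


def normalize_signal(obs: SubcodonSignal, rand: SubcodonSignal) -> SubcodonSignal:
    """Divide observed by random-control signal and renormalize to sum 1.

    norm(i) = (obs(i)/rand(i)) / sum_j obs(j)/rand(j). If any control
    component is 0, a symmetric pseudocount is added to all positions of
    both signals first (preserving uniformity).
    """
    if obs.total == 0:
        raise LowRibosomeSignal("all-zero observed signal cannot be normalized")
    o = obs.counts.astype(float)
    r = rand.counts.astype(float)
    if np.any(r == 0):
        o = o + PSEUDOCOUNT
        r = r + PSEUDOCOUNT
    ratio = o / r
    return SubcodonSignal(ratio / ratio.sum(), frame=obs.frame, kind="normalized")


def wre_by_frame(raw0: SubcodonSignal, prof: ReferenceProfile) -> np.ndarray:
    """Raw-proportion WRE for frames 0, 1, 2 from the frame-0 raw counts.

    Frame f's signal is the cyclic shift of the frame-0 counts; each is
    normalized to proportions before scoring.
    """
    if raw0.total == 0:
        raise LowRibosomeSignal("no ribosome signal in any frame")
    out = np.empty(3)
    for f in range(3):
        shifted = np.roll(raw0.counts, -f)
        out[f] = wre(shifted / shifted.sum(), prof)
    return out


def most_likely_reading_frame(raw0: SubcodonSignal, prof: ReferenceProfile) -> int:
    """argmax_f WRE(f); ties break to the lowest frame index."""
    return int(np.argmax(wre_by_frame(raw0, prof)))


def rps_posterior(theta: float, model_nc: DensityModel, model_pcg: DensityModel,
                  prior_nc: float = 0.5) -> tuple[float, bool]:
    """Posterior probability of being non-coding given the WRE value theta."""
    return bayes_posterior(model_nc.likelihood(theta), model_pcg.likelihood(theta), prior_nc)


def transcript_theta(tx: TranscriptModel, ribo, prof: ReferenceProfile,
                     rng_seed: int = 0, rc_replicates: int = DEFAULT_RC_REPLICATES,
                     ) -> tuple[np.ndarray | None, int | None, float | None]:
    """(wre_by_frame, mlrf, theta) for one transcript; (None, None, None) if LRT.

    The random control is seeded per transcript (CRC of the id mixed into
    the base seed) so results are order-independent and reproducible.
    """
    raw0 = count_subcodon(ribo, tx, frame=0, collapse=True)
    if raw0.total == 0:
        return None, None, None
    per_frame = wre_by_frame(raw0, prof)
    mlrf = int(np.argmax(per_frame))
    raw_mlrf = SubcodonSignal(np.roll(raw0.counts, -mlrf), frame=mlrf)
    if np.any(raw_mlrf.counts == 0):
        return per_frame, mlrf, None
    seed = (rng_seed + zlib.crc32(tx.transcript_id.encode())) % (2**31)
    rand = random_control(raw_mlrf.total, seed, rc_replicates)
    norm = normalize_signal(raw_mlrf, rand)
    return per_frame, mlrf, wre(norm, prof)


def classify_rps(tx: TranscriptModel, ribo, prof: ReferenceProfile,
                 model_nc: DensityModel, model_pcg: DensityModel,
                 cutoff: float = 0.5, prior_nc: float = 0.5,
                 rng_seed: int = 0, rc_replicates: int = DEFAULT_RC_REPLICATES) -> RPSResult:
    """Full step-1 call for one transcript.

    Routing: LRT if any raw sub-codon count at the MLRF is 0 (including the
    no-reads case); otherwise mRNA when RPS < cutoff, ncRNA when >= cutoff.
    ncRNA and LRT transcripts proceed to step 2.
    """
    per_frame, mlrf, theta = transcript_theta(tx, ribo, prof, rng_seed, rc_replicates)
    if theta is None:
        return RPSResult(tx.transcript_id, per_frame, mlrf, None, None, ROUTE_LRT)
    rps, degenerate = rps_posterior(theta, model_nc, model_pcg, prior_nc)
    routing = ROUTE_MRNA if rps < cutoff else ROUTE_NCRNA
    return RPSResult(tx.transcript_id, per_frame, mlrf, theta, rps, routing, degenerate)
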