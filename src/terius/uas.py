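"""Step 2 — UPF1 association scoring (UAS).

UPF1 relocates to 3'UTRs in a translation-dependent manner, so an
assembled "lncRNA" that is really a stray fragment of an mRNA's 3'UTR
carries disproportionate UPF1 CLIP signal for its expression level. The
association statistic is

    theta = ln(CLIP RPM / RNA RPM)

computed over a transcript's exonic span. Transcripts with exactly zero
CLIP signal get a ZERO flag instead of a theta; because the two classes
differ strongly in how often that happens, the per-class zero fraction is
part of the model and substitutes for the density likelihood in the
posterior. Training negatives are built by fragmenting annotated 3'UTRs
into pieces length-matched pairwise to the lncRNA positives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation import GenomicInterval, TranscriptModel, TranscriptSet
from .model import DensityModel, average_models, bayes_posterior, kde_fit, nested_cv_5x2
from .signals import ExpressionLevel

logger = logging.getLogger("terius")

LABEL_LNCRNA = "lncRNA"
LABEL_UTR3 = "UTR3_fragment"

RNA_RPM_FLOOR = 0.3  # training expression filter


class UnexpressedTranscript(ValueError):
    """RNA RPM is 0: the association ratio is undefined."""


@dataclass
class UTRFragment:
    """A random 3'UTR slice length-matched to one lncRNA."""

    source_gene: str
    interval: list[GenomicInterval]
    matched_lnc_id: str
    length: int

    def __post_init__(self) -> None:
        if self.length != sum(len(iv) for iv in self.interval):
            raise ValueError("fragment length does not match its intervals")


@dataclass(frozen=True)
class AssociationObservation:
    """One transcript's UPF1-association measurement."""

    id: str
    clip_rpm: float
    rna_rpm: float
    theta: float | None  # None encodes the ZERO flag (no CLIP signal at all)

    @property
    def is_zero(self) -> bool:
        return self.theta is None


@dataclass
class UASModel:
    """Class-conditional densities over theta plus per-class zero fractions."""

    density_lnc: DensityModel
    density_utr: DensityModel
    zero_frac_lnc: float
    zero_frac_utr: float

    def __post_init__(self) -> None:
        for name in ("zero_frac_lnc", "zero_frac_utr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# Training-set construction: pairwise length-matched 3'UTR fragments
# ---------------------------------------------------------------------------

def fragment_utr3(utr_set: TranscriptSet, lnc_set: TranscriptSet,
                  rng_seed: int) -> list[UTRFragment]:
    """Cut one random 3'UTR fragment per lncRNA, length-matched exactly.

    lncRNAs are processed in descending spliced length, each paired without
    replacement with a uniformly random 3'UTR donor still long enough; the
    fragment start is uniform within the donor UTR (spliced coordinates,
    mapped back to genomic intervals). lncRNAs with no eligible donor are
    left unpaired and logged.
    """
    rng = np.random.default_rng(rng_seed)
    donors = sorted(
        (tx for tx in utr_set if tx.utr3),
        key=lambda t: (t.utr3_spliced_length, t.transcript_id),
    )
    donor_lens = [t.utr3_spliced_length for t in donors]
    available = list(range(len(donors)))
    lncs = sorted(lnc_set, key=lambda t: (-t.spliced_length, t.transcript_id))
    fragments: list[UTRFragment] = []
    unpaired = 0
    for lnc in lncs:
        length = lnc.spliced_length
        eligible = [i for i in available if donor_lens[i] >= length]
        if not eligible:
            unpaired += 1
            continue
        pick = eligible[int(rng.integers(len(eligible)))]
        available.remove(pick)
        donor = donors[pick]
        # treat the donor 3'UTR as its own spliced coordinate system
        utr_model = TranscriptModel(
            f"{donor.transcript_id}__utr3", donor.gene_id, list(donor.utr3)
        )
        start = int(rng.integers(utr_model.spliced_length - length + 1))
        fragments.append(
            UTRFragment(
                source_gene=donor.gene_id,
                interval=utr_model.spliced_slice(start, start + length),
                matched_lnc_id=lnc.transcript_id,
                length=length,
            )
        )
    if unpaired:
        logger.info("fragment_utr3: %d lncRNAs had no 3'UTR donor long enough", unpaired)
    return fragments


# ---------------------------------------------------------------------------
# Association statistic and model
# ---------------------------------------------------------------------------

def association_observation(id: str, clip: ExpressionLevel, rna: ExpressionLevel) -> AssociationObservation:
    """theta = ln(CLIP RPM / RNA RPM); zero CLIP signal raises the ZERO flag."""
    if rna.rpm == 0:
        raise UnexpressedTranscript(f"{id}: RNA RPM is 0")
    if clip.rpm == 0:
        return AssociationObservation(id, 0.0, rna.rpm, None)
    return AssociationObservation(id, clip.rpm, rna.rpm, math.log(clip.rpm / rna.rpm))


def _as_replicates(obs) -> list[list[AssociationObservation]]:
    if obs and isinstance(obs[0], AssociationObservation):
        return [list(obs)]
    return [list(rep) for rep in obs]


def fit_uas_model(lnc_obs, utr_obs, hyper: dict | None = None,
                  rng_seed: int = 0) -> UASModel:
    """Fit the two-class density-plus-zero-fraction model.

    Accepts flat observation lists or lists of replicate lists (one per
    fragmentation replicate); replicate densities are averaged pointwise
    and zero fractions averaged. Hyperparameters come from a 5 x 2 nested
    CV over the pooled non-zero thetas unless given explicitly.
    """
    lnc_reps = _as_replicates(lnc_obs)
    utr_reps = _as_replicates(utr_obs)
    if len(lnc_reps) != len(utr_reps):
        raise ValueError("lnc and utr replicate counts differ")

    def thetas(rep):
        return np.array([o.theta for o in rep if not o.is_zero])

    pooled_lnc = np.concatenate([thetas(r) for r in lnc_reps])
    pooled_utr = np.concatenate([thetas(r) for r in utr_reps])
    if len(pooled_lnc) < 2 or len(pooled_utr) < 2:
        raise ValueError("each class needs >= 2 non-zero theta observations")
    if hyper is None:
        hyper = nested_cv_5x2(pooled_lnc, pooled_utr, rng_seed=rng_seed).chosen_hyper
    lnc_models, utr_models, zf_lnc, zf_utr = [], [], [], []
    for lrep, urep in zip(lnc_reps, utr_reps):
        tl, tu = thetas(lrep), thetas(urep)
        if len(tl) == 0 or len(tu) == 0:
            raise ValueError("a replicate class is entirely ZERO-flagged")
        lnc_models.append(kde_fit(tl, hyper["kernel"], hyper["bandwidth"], hyper["adjust"]))
        utr_models.append(kde_fit(tu, hyper["kernel"], hyper["bandwidth"], hyper["adjust"]))
        zf_lnc.append(sum(o.is_zero for o in lrep) / len(lrep))
        zf_utr.append(sum(o.is_zero for o in urep) / len(urep))
    return UASModel(
        density_lnc=average_models(lnc_models),
        density_utr=average_models(utr_models),
        zero_frac_lnc=float(np.mean(zf_lnc)),
        zero_frac_utr=float(np.mean(zf_utr)),
    )


def uas_posterior(obs: AssociationObservation, model: UASModel,
                  prior_lnc: float = 0.5) -> tuple[float, bool]:
    """Posterior probability the observation is a bona fide lncRNA.

    Non-zero theta uses the fitted densities; a ZERO-flagged observation
    substitutes the per-class zero fractions for the likelihoods.
    """
    if obs.is_zero:
        return bayes_posterior(model.zero_frac_lnc, model.zero_frac_utr, prior_lnc)
    return bayes_posterior(
        model.density_lnc.likelihood(obs.theta),
        model.density_utr.likelihood(obs.theta),
        prior_lnc,
    )


def classify_uas(obs: AssociationObservation, model: UASModel,
                 cutoff: float = 0.5, prior_lnc: float = 0.5) -> tuple[str, float, bool]:
    """(label, uas, degenerate): lncRNA when UAS >= cutoff, else 3'UTR fragment."""
    uas, degenerate = uas_posterior(obs, model, prior_lnc)
    label = LABEL_LNCRNA if uas >= cutoff else LABEL_UTR3
    return label, uas, degenerate


def filter_expressed(obs_list: Sequence[AssociationObservation],
                     floor: float = RNA_RPM_FLOOR) -> list[AssociationObservation]:
    """Keep observations whose RNA RPM meets the training expression floor."""
    return [o for o in obs_list if o.rna_rpm >= floor]
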