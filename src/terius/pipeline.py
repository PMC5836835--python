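"""The two-step ensemble: RPS routing, then UAS refinement.

Every candidate transcript is scored by ribosome periodicity first.
Transcripts called coding become mRNA and stop there; transcripts called
non-coding, and those with too little ribosome signal to score (LRT),
continue to the UPF1-association step, which separates bona fide lncRNAs
from 3'UTR fragments. Candidates unexpressed in RNA-seq at step 2 are
outside the association model's domain and get an explicit
``unclassified_unexpressed`` label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptSet
from .model import CVReport, DensityModel, load_model_file, save_model_file, train_density_pair
from .rps import (
    ROUTE_LRT,
    ROUTE_MRNA,
    ReferenceProfile,
    classify_rps,
    transcript_theta,
)
from .signals import ReadIndex, compute_rpm
from .simulate import LABEL_LNCRNA, LABEL_MRNA, LABEL_UTR3, LabeledFixture
from .uas import AssociationObservation, UASModel, association_observation, classify_uas, fit_uas_model

logger = logging.getLogger("terius")

LABEL_UNEXPRESSED = "unclassified_unexpressed"


@dataclass
class PipelineConfig:
    """Tunable knobs of the ensemble; defaults are the method's standard values."""

    rps_cutoff: float = 0.5
    uas_cutoff: float = 0.5
    prior_nc: float = 0.5
    prior_lnc: float = 0.5
    rc_replicates: int = 30
    rng_seed: int = 0
    rna_rpm_floor: float | None = None  # optional classification-time expression floor


@dataclass
class RPSModelBundle:
    """Everything step 1 needs: reference profile plus class densities."""

    profile: ReferenceProfile
    density_nc: DensityModel
    density_pcg: DensityModel
    genome_build: str = "unknown"

    def save(self, path: str) -> None:
        meta = {
            "kind": "rps",
            "log_base": "e",
            "genome_build": self.genome_build,
            "ribo_cds": ",".join(repr(float(x)) for x in self.profile.ribo_cds),
            "rna_cds": ",".join(repr(float(x)) for x in self.profile.rna_cds),
        }
        save_model_file(path, {"nc": self.density_nc, "pcg": self.density_pcg}, meta)

    @classmethod
    def load(cls, path: str) -> "RPSModelBundle":
        densities, meta = load_model_file(path)
        if meta.get("kind") != "rps":
            raise ValueError(f"{path}: not an RPS model file")
        prof = ReferenceProfile(
            np.array([float(x) for x in meta["ribo_cds"].split(",")]),
            np.array([float(x) for x in meta["rna_cds"].split(",")]),
        )
        return cls(prof, densities["nc"], densities["pcg"], meta.get("genome_build", "unknown"))


def save_uas_model(model: UASModel, path: str, genome_build: str = "unknown") -> None:
    meta = {
        "kind": "uas",
        "log_base": "e",
        "genome_build": genome_build,
        "zero_frac_lnc": repr(model.zero_frac_lnc),
        "zero_frac_utr": repr(model.zero_frac_utr),
    }
    save_model_file(path, {"lnc": model.density_lnc, "utr": model.density_utr}, meta)


def load_uas_model(path: str) -> tuple[UASModel, str]:
    densities, meta = load_model_file(path)
    if meta.get("kind") != "uas":
        raise ValueError(f"{path}: not a UAS model file")
    model = UASModel(
        densities["lnc"], densities["utr"],
        float(meta["zero_frac_lnc"]), float(meta["zero_frac_utr"]),
    )
    return model, meta.get("genome_build", "unknown")


@dataclass
class ClassificationRecord:
    """Per-transcript output of the full two-step run."""

    transcript_id: str
    wre: float | None
    mlrf: int | None
    rps: float | None
    routing: str
    theta: float | None
    uas: float | None
    final_label: str


def _check_build(annot_build: str, model_build: str, what: str) -> None:
    known = {b for b in (annot_build, model_build) if b not in ("", "unknown")}
    if len(known) == 2:
        raise ValueError(
            f"genome build mismatch: annotation is {annot_build!r} but {what} "
            f"model was trained on {model_build!r}"
        )


def run_terius(
    annot: TranscriptSet,
    ribo: ReadIndex,
    rna: ReadIndex,
    clip: ReadIndex,
    rps_model: RPSModelBundle,
    uas_model: UASModel,
    config: PipelineConfig | None = None,
) -> list[ClassificationRecord]:
    """Classify every transcript as mRNA, lncRNA, or 3'UTR fragment."""
    cfg = config or PipelineConfig()
    _check_build(annot.genome_build, rps_model.genome_build, "RPS")
    rna_lib = max(rna.n_reads, 1)
    clip_lib = max(clip.n_reads, 1)
    records: list[ClassificationRecord] = []
    for tx in annot:
        r = classify_rps(
            tx, ribo, rps_model.profile, rps_model.density_nc, rps_model.density_pcg,
            cutoff=cfg.rps_cutoff, prior_nc=cfg.prior_nc,
            rng_seed=cfg.rng_seed, rc_replicates=cfg.rc_replicates,
        )
        if r.routing == ROUTE_MRNA:
            records.append(ClassificationRecord(
                tx.transcript_id, r.wre, r.mlrf, r.rps, r.routing, None, None, LABEL_MRNA))
            continue
        rna_rpm = compute_rpm(rna, tx.exons, rna_lib)
        floor = cfg.rna_rpm_floor or 0.0
        if rna_rpm.rpm == 0 or rna_rpm.rpm < floor:
            records.append(ClassificationRecord(
                tx.transcript_id, r.wre, r.mlrf, r.rps, r.routing, None, None, LABEL_UNEXPRESSED))
            continue
        clip_rpm = compute_rpm(clip, tx.exons, clip_lib)
        obs = association_observation(tx.transcript_id, clip_rpm, rna_rpm)
        label, uas, _ = classify_uas(obs, uas_model, cfg.uas_cutoff, cfg.prior_lnc)
        records.append(ClassificationRecord(
            tx.transcript_id, r.wre, r.mlrf, r.rps, r.routing, obs.theta, uas, label))
    for lab, n in summarize(records)["count"].items():
        logger.info("run_terius: %s: %d", lab, n)
    return records


def records_to_frame(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "wre": r.wre,
                "mlrf": r.mlrf,
                "rps": r.rps,
                "routing": r.routing,
                "theta": r.theta,
                "uas": r.uas,
                "final_label": r.final_label,
            }
            for r in records
        ]
    )


def summarize(records: Sequence[ClassificationRecord]) -> pd.DataFrame:
    """Per-label counts and percentages of the final classification."""
    if not records:
        raise ValueError("summarize: no records")
    labels = pd.Series([r.final_label for r in records])
    counts = labels.value_counts().sort_index()
    return pd.DataFrame({"count": counts, "percent": 100.0 * counts / len(labels)})


# ---------------------------------------------------------------------------
# Training on a labeled fixture (synthetic or user-supplied truth)
# ---------------------------------------------------------------------------

@dataclass
class TrainedModels:
    rps: RPSModelBundle
    uas: UASModel
    rps_cv: CVReport | None = None
    nc_thetas: dict[str, float] = field(default_factory=dict)
    pcg_thetas: dict[str, float] = field(default_factory=dict)
    lnc_obs: list[AssociationObservation] = field(default_factory=list)
    utr_obs: list[AssociationObservation] = field(default_factory=list)


def train_from_fixture(
    fx: LabeledFixture,
    rng_seed: int = 0,
    n_replicates: int = 50,
    hyper_grid: list[dict] | None = None,
    rps_hyper: dict | None = None,
    uas_hyper: dict | None = None,
    rc_replicates: int = 30,
) -> TrainedModels:
    """Train both classifiers from a labeled fixture's reads and annotation.

    Step 1: build the CDS reference profile from the coding transcripts,
    compute WRE theta for every scoreable transcript (those with signal in
    all three sub-codon positions at the MLRF), and fit replicate-averaged
    class densities with nested-CV hyperparameter selection. Step 2:
    compute CLIP/RNA association observations for the non-coding classes
    and fit the density-plus-zero-fraction model.
    """
    from .annotation import TranscriptSet as TS
    from .rps import build_reference_profile

    ribo = ReadIndex(fx.ribo_reads)
    rna = ReadIndex(fx.rna_reads)
    clip = ReadIndex(fx.clip_reads)

    cds_set = TS(genome_build=fx.annotation.genome_build)
    for tx in fx.annotation:
        if tx.cds:
            cds_set.add(tx)
    profile = build_reference_profile(cds_set, ribo, rna)

    nc_thetas: dict[str, float] = {}
    pcg_thetas: dict[str, float] = {}
    for tx in fx.annotation:
        _, _, theta = transcript_theta(tx, ribo, profile, rng_seed, rc_replicates)
        if theta is None:
            continue  # training mirrors classification: LRT transcripts are not scoreable
        if fx.true_labels[tx.transcript_id] == LABEL_MRNA:
            pcg_thetas[tx.transcript_id] = theta
        else:
            nc_thetas[tx.transcript_id] = theta
    density_nc, density_pcg, report = train_density_pair(
        list(nc_thetas.values()), list(pcg_thetas.values()),
        n_replicates=n_replicates, rng_seed=rng_seed,
        hyper_grid=hyper_grid, hyper=rps_hyper,
    )
    bundle = RPSModelBundle(profile, density_nc, density_pcg, fx.annotation.genome_build)

    rna_lib = max(rna.n_reads, 1)
    clip_lib = max(clip.n_reads, 1)
    lnc_obs: list[AssociationObservation] = []
    utr_obs: list[AssociationObservation] = []
    for tx in fx.annotation:
        label = fx.true_labels[tx.transcript_id]
        if label not in (LABEL_LNCRNA, LABEL_UTR3):
            continue
        rna_rpm = compute_rpm(rna, tx.exons, rna_lib)
        if rna_rpm.rpm == 0:
            continue
        clip_rpm = compute_rpm(clip, tx.exons, clip_lib)
        obs = association_observation(tx.transcript_id, clip_rpm, rna_rpm)
        (lnc_obs if label == LABEL_LNCRNA else utr_obs).append(obs)
    uas_model = fit_uas_model(lnc_obs, utr_obs, hyper=uas_hyper, rng_seed=rng_seed)
    return TrainedModels(bundle, uas_model, report, nc_thetas, pcg_thetas, lnc_obs, utr_obs)
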