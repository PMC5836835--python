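"""Density estimation, nested cross-validation, and ROC evaluation.

Both classification steps share the same statistical machinery: each class
of a two-class problem gets a one-dimensional kernel density estimate of
its score distribution, hyperparameters (kernel, bandwidth rule, bandwidth
adjustment) are selected by 5 x 2 nested cross-validation maximizing inner
AUC, and the final per-class density is the pointwise mean over replicate
balanced training cohorts. Class-conditional likelihoods are read off the
fitted densities and combined by Bayes' rule into a posterior.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KernelDensity

DEFAULT_HYPER_GRID: list[dict] = [
    {"kernel": k, "bandwidth": b, "adjust": a}
    for k in ("gaussian", "epanechnikov")
    for b in ("silverman", "scott")
    for a in (0.5, 1.0, 2.0)
]

GRID_POINTS = 512
GRID_PAD_BANDWIDTHS = 3.0


def bandwidth_from_rule(values: np.ndarray, rule) -> float:
    """Effective kernel bandwidth from a rule name or an explicit number.

    ``silverman``: 0.9 min(sd, IQR/1.34) n^(-1/5); ``scott``: sd n^(-1/5).
    """
    if isinstance(rule, (int, float)):
        if rule <= 0:
            raise ValueError("bandwidth must be positive")
        return float(rule)
    n = len(values)
    sd = float(np.std(values, ddof=1))
    if rule == "scott":
        return sd * n ** (-0.2)
    if rule == "silverman":
        iqr = float(np.subtract(*np.percentile(values, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        return 0.9 * spread * n ** (-0.2)
    raise ValueError(f"unknown bandwidth rule {rule!r}")


@dataclass
class DensityModel:
    """A 1-D density on a grid, evaluable anywhere by linear interpolation.

    Outside the grid the likelihood is 0 (no extrapolation); downstream
    posteriors fall back to 0.5 when both class likelihoods vanish.
    """

    grid: np.ndarray
    density: np.ndarray
    kernel: str = "gaussian"
    bandwidth: object = "silverman"
    adjust: float = 1.0
    effective_bandwidth: float = float("nan")

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise ValueError("grid and density must be 1-D vectors of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def likelihood(self, theta) -> np.ndarray | float:
        out = np.interp(np.asarray(theta, dtype=float), self.grid, self.density, left=0.0, right=0.0)
        return float(out) if np.isscalar(theta) else out

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def kde_fit(values: Sequence[float], kernel: str = "gaussian",
            bandwidth="silverman", adjust: float = 1.0,
            grid_points: int = GRID_POINTS) -> DensityModel:
    """Fit a kernel density estimate and evaluate it on a regular grid.

    The grid spans [min - 3h, max + 3h] with h the effective bandwidth
    (rule value x adjust), wide enough that the density decays to ~0 at
    the edges for every supported kernel.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("kde_fit needs at least 2 finite values")
    if np.ptp(x) == 0 and not isinstance(bandwidth, (int, float)):
        raise ValueError("kde_fit: zero-variance sample needs an explicit bandwidth")
    h = bandwidth_from_rule(x, bandwidth) * adjust
    if h <= 0:
        raise ValueError("effective bandwidth must be positive")
    grid = np.linspace(x.min() - GRID_PAD_BANDWIDTHS * h, x.max() + GRID_PAD_BANDWIDTHS * h, grid_points)
    kde = KernelDensity(kernel=kernel, bandwidth=h).fit(x[:, None])
    density = np.exp(kde.score_samples(grid[:, None]))
    return DensityModel(grid, density, kernel=kernel, bandwidth=bandwidth,
                        adjust=adjust, effective_bandwidth=h)


def average_models(models: Sequence[DensityModel]) -> DensityModel:
    """Pointwise mean of densities on the union grid of all models."""
    if not models:
        raise ValueError("average_models needs at least one model")
    if len(models) == 1:
        return models[0]
    grid = np.unique(np.concatenate([m.grid for m in models]))
    density = np.mean([m.likelihood(grid) for m in models], axis=0)
    avg = DensityModel(grid, density, kernel=models[0].kernel,
                       bandwidth=models[0].bandwidth, adjust=models[0].adjust,
                       effective_bandwidth=float(np.mean([m.effective_bandwidth for m in models])))
    total = avg.integral()
    if not 0.95 <= total <= 1.05:
        raise ValueError(f"averaged density integral {total:.4f} far from 1")
    return avg


def bayes_posterior(lik_pos: float, lik_neg: float, prior_pos: float = 0.5) -> tuple[float, bool]:
    """Two-class posterior P(pos | theta); returns (posterior, degenerate_flag).

    When both likelihoods are 0 (theta outside both fitted supports) the
    posterior is defined as 0.5 and flagged.
    """
    if not 0.0 < prior_pos < 1.0:
        raise ValueError("prior must be in (0, 1)")
    num = lik_pos * prior_pos
    den = num + lik_neg * (1.0 - prior_pos)
    if den == 0.0:
        return 0.5, True
    return num / den, False


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank statistic; ties count half)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def balanced_cohorts(pos: Sequence[float], neg: Sequence[float],
                     n_replicates: int, rng_seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Replicate cohorts: all positives plus an equal-size negative subsample.

    Negatives are drawn without replacement per cohort (seeded), balancing
    a large negative class against a small positive one.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(neg) < len(pos):
        raise ValueError("balanced_cohorts requires |neg| >= |pos|")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_replicates):
        sub = rng.choice(neg, size=len(pos), replace=False)
        out.append((pos.copy(), sub))
    return out


@dataclass
class CVReport:
    """Outer-fold AUCs and the winning hyperparameters of a nested CV run."""

    folds: list[dict] = field(default_factory=list)
    chosen_hyper: dict = field(default_factory=dict)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f["auc"] for f in self.folds]))


def _posterior_scores(theta: np.ndarray, m_pos: DensityModel, m_neg: DensityModel) -> np.ndarray:
    lp = m_pos.likelihood(theta)
    ln = m_neg.likelihood(theta)
    den = lp + ln
    out = np.full(len(theta), 0.5)
    nz = den > 0
    out[nz] = lp[nz] / den[nz]
    return out


def _fit_pair(pos, neg, hyper) -> tuple[DensityModel, DensityModel]:
    return (
        kde_fit(pos, hyper["kernel"], hyper["bandwidth"], hyper["adjust"]),
        kde_fit(neg, hyper["kernel"], hyper["bandwidth"], hyper["adjust"]),
    )


def nested_cv_5x2(pos: Sequence[float], neg: Sequence[float],
                  hyper_grid: list[dict] | None = None,
                  rng_seed: int = 0) -> CVReport:
    """5 repetitions of stratified 2-fold CV with an inner 2-fold hyper search.

    Within each outer training half the inner folds select the kernel /
    bandwidth-rule / adjust combination maximizing inner AUC; the held-out
    half is scored with class-posterior probabilities (prior 0.5) to give
    the fold AUC. The report's chosen_hyper is the modal winner over the
    ten outer folds.
    """
    hyper_grid = hyper_grid or DEFAULT_HYPER_GRID
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 10 or len(neg) < 10:
        raise ValueError("nested_cv_5x2 needs >= 10 samples per class")
    x = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    report = CVReport()
    for rep in range(5):
        outer = StratifiedKFold(n_splits=2, shuffle=True, random_state=rng_seed + rep)
        for fold, (tr, te) in enumerate(outer.split(x[:, None], y)):
            xtr, ytr, xte, yte = x[tr], y[tr], x[te], y[te]
            best_hyper, best_auc = None, -np.inf
            inner = StratifiedKFold(n_splits=2, shuffle=True,
                                    random_state=10_000 + rng_seed + 10 * rep + fold)
            inner_splits = list(inner.split(xtr[:, None], ytr))
            for hyper in hyper_grid:
                aucs = []
                for itr, ite in inner_splits:
                    try:
                        mp, mn = _fit_pair(xtr[itr][ytr[itr] == 1], xtr[itr][ytr[itr] == 0], hyper)
                    except ValueError:
                        aucs.append(0.0)
                        continue
                    s = _posterior_scores(xtr[ite], mp, mn)
                    aucs.append(roc_auc(s, ytr[ite]))
                mean_inner = float(np.mean(aucs))
                if mean_inner > best_auc:
                    best_auc, best_hyper = mean_inner, hyper
            mp, mn = _fit_pair(xtr[ytr == 1], xtr[ytr == 0], best_hyper)
            auc = roc_auc(_posterior_scores(xte, mp, mn), yte)
            report.folds.append({"rep": rep, "fold": fold, "auc": auc, "hyper": best_hyper})
    winner = Counter(tuple(sorted(f["hyper"].items())) for f in report.folds).most_common(1)[0][0]
    report.chosen_hyper = dict(winner)
    return report


def train_density_pair(pos: Sequence[float], neg: Sequence[float],
                       n_replicates: int = 50, rng_seed: int = 0,
                       hyper_grid: list[dict] | None = None,
                       hyper: dict | None = None) -> tuple[DensityModel, DensityModel, CVReport | None]:
    """Full training recipe: nested-CV hyper selection, then replicate-averaged fit.

    Hyperparameters are chosen by :func:`nested_cv_5x2` on the full data
    unless ``hyper`` is given explicitly. The positive-class density is fit
    once on all positives; the negative-class density is the mean over
    ``n_replicates`` balanced cohorts of negative subsamples.
    """
    report = None
    if hyper is None:
        report = nested_cv_5x2(pos, neg, hyper_grid, rng_seed)
        hyper = report.chosen_hyper
    if len(neg) >= len(pos):
        cohorts = balanced_cohorts(pos, neg, n_replicates, rng_seed)
    else:  # positives outnumber negatives: subsample positives instead
        cohorts = [(p, n) for n, p in balanced_cohorts(neg, pos, n_replicates, rng_seed)]
    pos_models, neg_models = [], []
    for cpos, cneg in cohorts:
        pos_models.append(kde_fit(cpos, hyper["kernel"], hyper["bandwidth"], hyper["adjust"]))
        neg_models.append(kde_fit(cneg, hyper["kernel"], hyper["bandwidth"], hyper["adjust"]))
    return average_models(pos_models), average_models(neg_models), report


# ---------------------------------------------------------------------------
# Model file serialization
# ---------------------------------------------------------------------------

def save_model_file(path: str, densities: dict[str, DensityModel], meta: dict) -> None:
    """Self-describing tabular model file: header metadata, then grid rows.

    ``meta`` always records the log base used for the score so models are
    portable across runs; extra keys (zero fractions, priors, training
    sizes) pass through verbatim.
    """
    with open(path, "w") as fh:
        fh.write("#terius_model\tversion=1\n")
        for k, v in meta.items():
            fh.write(f"#meta\t{k}={v}\n")
        for name, m in densities.items():
            fh.write(
                f"#density\tname={name}\tkernel={m.kernel}\tbandwidth={m.bandwidth}"
                f"\tadjust={m.adjust}\teffective_bandwidth={m.effective_bandwidth}\n"
            )
            for g, d in zip(m.grid, m.density):
                fh.write(f"{name}\t{float(g)!r}\t{float(d)!r}\n")


def load_model_file(path: str) -> tuple[dict[str, DensityModel], dict]:
    meta: dict[str, str] = {}
    attrs: dict[str, dict] = {}
    rows: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#terius_model"):
            raise ValueError(f"{path}: not a terius model file")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#meta\t"):
                k, v = line.split("\t", 1)[1].split("=", 1)
                meta[k] = v
            elif line.startswith("#density\t"):
                kv = dict(item.split("=", 1) for item in line.split("\t")[1:])
                attrs[kv["name"]] = kv
            elif line:
                name, g, d = line.split("\t")
                rows.setdefault(name, []).append((float(g), float(d)))
    densities = {}
    for name, pts in rows.items():
        a = attrs[name]
        grid, dens = map(np.asarray, zip(*pts))
        bw = a["bandwidth"]
        try:
            bw = float(bw)
        except ValueError:
            pass
        densities[name] = DensityModel(grid, dens, kernel=a["kernel"], bandwidth=bw,
                                       adjust=float(a["adjust"]),
                                       effective_bandwidth=float(a["effective_bandwidth"]))
    return densities, meta
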