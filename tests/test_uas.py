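"""3'UTR fragmentation, association statistic, and UAS posterior."""

import math

import numpy as np
import pytest

from terius import (
    association_observation,
    classify_uas,
    fit_uas_model,
    fragment_utr3,
    uas_posterior,
)
from terius.annotation import GenomicInterval
from terius.signals import ExpressionLevel
from terius.uas import (
    LABEL_LNCRNA,
    LABEL_UTR3,
    AssociationObservation,
    UnexpressedTranscript,
    filter_expressed,
)

from _helpers import make_set, make_tx


def el(raw, lib=1_000_000):
    return ExpressionLevel(raw_count=raw, library_size=lib)


def make_utr_donor(tid, start, utr_len, gene=None):
    """Coding transcript whose 3'UTR spans utr_len nt after a 90-nt CDS."""
    tx = make_tx(tid, [(start, start + 90 + utr_len)], gene=gene, cds=[(start, start + 90)])
    tx.utr3 = [GenomicInterval("chr1", start + 90, start + 90 + utr_len, "+")]
    return tx


class TestAssociationObservation:
    def test_equal_rpm_gives_zero_theta(self):
        obs = association_observation("x", el(10), el(10))
        assert obs.theta == pytest.approx(0.0)

    def test_zero_clip_raises_the_zero_flag(self):
        obs = association_observation("x", el(0), el(5))
        assert obs.is_zero and obs.theta is None

    def test_log_ratio_arithmetic(self):
        obs = association_observation("x", el(2), el(8))
        assert obs.theta == pytest.approx(math.log(0.25), abs=1e-12)

    def test_unexpressed_transcript_rejected(self):
        with pytest.raises(UnexpressedTranscript):
            association_observation("x", el(2), el(0))

    def test_expression_floor_filter_is_inclusive(self):
        kept = filter_expressed([
            AssociationObservation("a", 1.0, 0.3, 0.0),
            AssociationObservation("b", 1.0, 0.29, 0.0),
        ])
        assert [o.id for o in kept] == ["a"]


class TestFragmentation:
    def test_equal_lengths_force_whole_utr(self):
        lnc = make_tx("lnc1", [(5000, 5500)])
        donor = make_utr_donor("m1", 0, 500)
        (frag,) = fragment_utr3(make_set(donor), make_set(lnc), rng_seed=0)
        assert frag.length == 500
        assert [(iv.start, iv.end) for iv in frag.interval] == [(90, 590)]

    def test_seeded_determinism(self):
        lnc = make_tx("lnc1", [(5000, 5300)])
        donor = make_utr_donor("m1", 0, 1000)
        a = fragment_utr3(make_set(donor), make_set(lnc), rng_seed=7)
        b = fragment_utr3(make_set(donor), make_set(lnc), rng_seed=7)
        assert [(f.interval[0].start, f.interval[0].end) for f in a] == [
            (f.interval[0].start, f.interval[0].end) for f in b
        ]

    def test_every_lncrna_with_a_donor_gets_one_fragment(self):
        rng = np.random.default_rng(1)
        lncs, donors = [], []
        for i in range(20):
            s = 100_000 + 3000 * i
            lncs.append(make_tx(f"lnc{i}", [(s, s + int(rng.integers(200, 900)))]))
            donors.append(make_utr_donor(f"m{i}", 3000 * i, 1000, gene=f"g{i}"))
        frags = fragment_utr3(make_set(*donors), make_set(*lncs), rng_seed=2)
        assert len(frags) == 20
        assert len({f.matched_lnc_id for f in frags}) == 20

    def test_lengths_match_pairwise_over_replicates(self):
        rng = np.random.default_rng(3)
        lncs = [
            make_tx(f"lnc{i}", [(100_000 + 2000 * i, 100_000 + 2000 * i + int(rng.integers(150, 950)))])
            for i in range(15)
        ]
        donors = [make_utr_donor(f"m{i}", 2000 * i, 1000, gene=f"g{i}") for i in range(15)]
        lnc_set, donor_set = make_set(*lncs), make_set(*donors)
        for seed in range(10):
            for frag in fragment_utr3(donor_set, lnc_set, rng_seed=seed):
                lnc = lnc_set[frag.matched_lnc_id]
                assert frag.length == lnc.spliced_length
                assert sum(iv.end - iv.start for iv in frag.interval) == lnc.spliced_length

    def test_fragment_stays_within_donor_utr(self):
        lnc = make_tx("lnc1", [(50_000, 50_400)])
        donor = make_utr_donor("m1", 0, 1000)
        for seed in range(5):
            (frag,) = fragment_utr3(make_set(donor), make_set(lnc), rng_seed=seed)
            for iv in frag.interval:
                assert 90 <= iv.start < iv.end <= 1090

    def test_lncrna_without_long_enough_donor_is_unpaired(self):
        lnc = make_tx("lnc1", [(50_000, 52_000)])  # 2000 nt, donor UTR only 500
        donor = make_utr_donor("m1", 0, 500)
        assert fragment_utr3(make_set(donor), make_set(lnc), rng_seed=0) == []


def synthetic_obs(rng, n, mean, zero_frac, prefix):
    n_zero = int(round(zero_frac * n))
    out = [AssociationObservation(f"{prefix}{i}", 0.0, 1.0, None) for i in range(n_zero)]
    out += [
        AssociationObservation(f"{prefix}{i}", 1.0, 1.0, float(t))
        for i, t in enumerate(rng.normal(mean, 1.0, size=n - n_zero), start=n_zero)
    ]
    return out


class TestFitUASModel:
    def test_zero_fraction_is_the_observed_ratio(self):
        rng = np.random.default_rng(4)
        lnc = synthetic_obs(rng, 100, -1.0, 0.25, "l")
        utr = synthetic_obs(rng, 100, 1.0, 0.0, "u")
        m = fit_uas_model(lnc, utr, hyper={"kernel": "gaussian", "bandwidth": "silverman", "adjust": 1.0})
        assert m.zero_frac_lnc == pytest.approx(0.25)
        assert m.zero_frac_utr == pytest.approx(0.0)

    def test_density_modes_land_on_the_correct_sides(self):
        rng = np.random.default_rng(5)
        lnc = synthetic_obs(rng, 300, -1.0, 0.0, "l")
        utr = synthetic_obs(rng, 300, 1.0, 0.0, "u")
        m = fit_uas_model(lnc, utr, hyper={"kernel": "gaussian", "bandwidth": "silverman", "adjust": 1.0})
        assert m.density_lnc.grid[np.argmax(m.density_lnc.density)] < 0
        assert m.density_utr.grid[np.argmax(m.density_utr.density)] > 0

    def test_identical_replicates_equal_single_fit(self):
        rng = np.random.default_rng(6)
        lnc = synthetic_obs(rng, 80, -1.0, 0.2, "l")
        utr = synthetic_obs(rng, 80, 1.0, 0.05, "u")
        hyper = {"kernel": "gaussian", "bandwidth": "silverman", "adjust": 1.0}
        single = fit_uas_model(lnc, utr, hyper=hyper)
        reps = fit_uas_model([lnc] * 10, [utr] * 10, hyper=hyper)
        assert np.allclose(reps.density_lnc.likelihood(single.density_lnc.grid),
                           single.density_lnc.density, atol=1e-9)
        assert reps.zero_frac_lnc == pytest.approx(single.zero_frac_lnc)

    def test_entirely_zero_class_is_an_error(self):
        rng = np.random.default_rng(7)
        lnc = synthetic_obs(rng, 50, -1.0, 1.0, "l")
        utr = synthetic_obs(rng, 50, 1.0, 0.0, "u")
        with pytest.raises(ValueError):
            fit_uas_model(lnc, utr, hyper={"kernel": "gaussian", "bandwidth": "silverman", "adjust": 1.0})


@pytest.fixture(scope="module")
def toy_uas_model():
    rng = np.random.default_rng(8)
    lnc = synthetic_obs(rng, 200, -1.5, 0.6, "l")
    utr = synthetic_obs(rng, 200, 0.5, 0.2, "u")
    return fit_uas_model(lnc, utr, hyper={"kernel": "gaussian", "bandwidth": "silverman", "adjust": 1.0})


class TestUASPosterior:
    def test_complement_sums_to_one_on_a_theta_sweep(self, toy_uas_model):
        m = toy_uas_model
        for theta in np.linspace(-4, 3, 50):
            obs = AssociationObservation("x", 1.0, 1.0, float(theta))
            p, _ = uas_posterior(obs, m)
            flipped = type(m)(m.density_utr, m.density_lnc, m.zero_frac_utr, m.zero_frac_lnc)
            q, _ = uas_posterior(obs, flipped)
            assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_zero_flag_uses_zero_fractions(self, toy_uas_model):
        m = type(toy_uas_model)(
            toy_uas_model.density_lnc, toy_uas_model.density_utr, 0.6, 0.2
        )
        obs = AssociationObservation("x", 0.0, 1.0, None)
        assert uas_posterior(obs, m)[0] == pytest.approx(0.75)

    def test_low_theta_favors_lncrna_high_theta_favors_utr(self, toy_uas_model):
        low, _ = uas_posterior(AssociationObservation("x", 1, 1, -1.5), toy_uas_model)
        high, _ = uas_posterior(AssociationObservation("x", 1, 1, 0.5), toy_uas_model)
        assert low > 0.5 > high

    def test_boundary_calls_lncrna_at_exact_cutoff(self, toy_uas_model):
        m = type(toy_uas_model)(
            toy_uas_model.density_lnc, toy_uas_model.density_utr, 0.5, 0.5
        )
        label, uas, _ = classify_uas(AssociationObservation("x", 0.0, 1.0, None), m)
        assert uas == pytest.approx(0.5) and label == LABEL_LNCRNA

    def test_high_clip_observation_called_utr_fragment(self, toy_uas_model):
        label, _, _ = classify_uas(AssociationObservation("x", 1, 1, 0.8), toy_uas_model)
        assert label == LABEL_UTR3
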