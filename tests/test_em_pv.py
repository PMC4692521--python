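"""EM mixture fitting and the CGM-WM partial-volume class."""

import numpy as np
import pytest

from neoribbon import em_pv
from neoribbon.io_core import (
    IntensityVolume,
    PHANTOM_CGM_LEFT,
    PHANTOM_WM,
    ProbabilityMaps,
    phantom_lut,
)


def two_class_image(means=(50.0, 150.0), sd=10.0, shape=(40, 40, 40), seed=1):
    rng = np.random.default_rng(seed)
    half = shape[0] // 2
    lab = (np.indices(shape)[0] >= half).astype(int)
    img = np.where(lab == 0, means[0], means[1]) + rng.normal(0, sd, shape)
    return IntensityVolume(img, np.eye(4)), lab


class TestFitEM:
    def test_two_class_mean_recovery_with_uniform_priors(self):
        img, _ = two_class_image()
        priors = ProbabilityMaps([0, 1], np.full((2,) + img.shape, 0.5))
        res = em_pv.fit_em_gmm(img, priors)
        means = sorted(c.mean for c in res.classes)
        assert abs(means[0] - 50) / 50 < 0.02
        assert abs(means[1] - 150) / 150 < 0.02
        assert res.converged

    def test_three_class_mean_recovery(self):
        rng = np.random.default_rng(4)
        shape = (42, 30, 30)
        lab = (np.indices(shape)[0] // 14).clip(0, 2)
        img = IntensityVolume(
            np.choose(lab, [60.0, 120.0, 190.0]) + rng.normal(0, 10, shape), np.eye(4)
        )
        priors = ProbabilityMaps([0, 1, 2], np.full((3,) + shape, 1 / 3))
        res = em_pv.fit_em_gmm(img, priors)
        for mean, truth in zip(sorted(c.mean for c in res.classes), (60, 120, 190)):
            assert abs(mean - truth) / truth < 0.02

    def test_log_likelihood_monotone(self):
        img, _ = two_class_image(seed=9)
        priors = ProbabilityMaps([0, 1], np.full((2,) + img.shape, 0.5))
        res = em_pv.fit_em_gmm(img, priors)
        trace = np.asarray(res.log_likelihood_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))

    def test_one_hot_prior_pins_posterior(self):
        img, _ = two_class_image()
        pri = np.full((2,) + img.shape, 0.5)
        pri[0, 3, 3, 3], pri[1, 3, 3, 3] = 1.0, 0.0
        res = em_pv.fit_em_gmm(img, ProbabilityMaps([0, 1], pri))
        assert res.posteriors[0][3, 3, 3] == pytest.approx(1.0, abs=1e-12)

    def test_posterior_normalization(self):
        img, _ = two_class_image(seed=2)
        priors = ProbabilityMaps([0, 1], np.full((2,) + img.shape, 0.5))
        res = em_pv.fit_em_gmm(img, priors)
        sums = res.posteriors.data.sum(axis=0)[res.mask]
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_all_zero_prior_rejected(self):
        img, _ = two_class_image()
        pri = np.full((2,) + img.shape, 0.5)
        pri[:, 0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="all-zero prior"):
            em_pv.fit_em_gmm(img, ProbabilityMaps([0, 1], pri), mask=np.ones(img.shape, bool))

    def test_needs_two_classes(self):
        img, _ = two_class_image()
        with pytest.raises(ValueError, match="2 classes"):
            em_pv.fit_em_gmm(img, ProbabilityMaps([0], np.ones((1,) + img.shape)))


class TestPVClass:
    def test_pv_prior_formula_at_overlap(self):
        shape = (6, 6, 6)
        pri = np.zeros((2,) + shape)
        pri[0], pri[1] = 0.5, 0.5
        pm = ProbabilityMaps([1, 2], pri)
        out, pv_id = em_pv.add_pv_class(pm, 1, 2, kappa=1.0)
        # pv = 1.0 * min(0.5, 0.5) = 0.5 before renormalization -> 1/3 after
        assert out[pv_id][3, 3, 3] == pytest.approx(0.5 / 1.5)
        np.testing.assert_allclose(out.data.sum(axis=0), 1.0, atol=1e-9)

    def test_pv_prior_zero_away_from_interface(self):
        shape = (10, 6, 6)
        pri = np.zeros((2,) + shape)
        pri[0, :5] = 1.0  # CGM left half
        pri[1, 5:] = 1.0  # WM right half
        out, pv_id = em_pv.add_pv_class(ProbabilityMaps([1, 2], pri), 1, 2, kappa=0.5)
        assert out[pv_id][0, 3, 3] == 0.0  # deep inside CGM
        assert out[pv_id][9, 3, 3] == 0.0  # deep inside WM
        assert out[pv_id][5, 3, 3] > 0.0  # interface band

    def test_kappa_validated(self):
        pri = ProbabilityMaps([1, 2], np.full((2, 4, 4, 4), 0.5))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="kappa"):
                em_pv.add_pv_class(pri, 1, 2, kappa=bad)

    @pytest.mark.parametrize(
        "cgm,wm,expect_mean,expect_var",
        [((100, 25), (160, 100), 130, 100), ((90, 64), (90, 64), 90, 64)],
    )
    def test_init_pv_params(self, cgm, wm, expect_mean, expect_var):
        pv = em_pv.init_pv_params(
            em_pv.GaussianClass(1, *cgm), em_pv.GaussianClass(2, *wm)
        )
        assert pv.mean == expect_mean
        assert pv.variance == expect_var


class TestMergePV:
    def test_merge_arithmetic_and_argmax(self):
        shape = (2, 2, 2)
        data = np.zeros((3,) + shape)
        data[0], data[1], data[2] = 0.40, 0.35, 0.25  # CGM, WM, PV
        res = em_pv.EMResult(
            ProbabilityMaps([2, 1, 9], data),
            [em_pv.GaussianClass(2, 90, 25), em_pv.GaussianClass(1, 140, 25), em_pv.GaussianClass(9, 115, 25)],
            mask=np.ones(shape, bool),
        )
        merged, labels = em_pv.merge_pv_into_wm(res, 9, 1, phantom_lut())
        assert merged[1][0, 0, 0] == pytest.approx(0.60)
        assert 9 not in merged.class_ids
        assert np.all(labels.data == 1)  # merged WM 0.60 beats CGM 0.40

    def test_zero_pv_mass_is_identity(self):
        rng = np.random.default_rng(3)
        shape = (4, 4, 4)
        base = rng.dirichlet((2, 2), size=shape).transpose(3, 0, 1, 2)
        data = np.concatenate([base, np.zeros((1,) + shape)])
        res = em_pv.EMResult(
            ProbabilityMaps([1, 2, 9], data),
            [em_pv.GaussianClass(i, 100, 25) for i in (1, 2, 9)],
            mask=np.ones(shape, bool),
        )
        merged, labels = em_pv.merge_pv_into_wm(res, 9, 1, phantom_lut())
        expect = em_pv.hard_labels(ProbabilityMaps([1, 2], base), phantom_lut(), np.ones(shape, bool))
        assert np.array_equal(labels.data, expect.data)

    def test_argmax_tie_breaks_to_lowest_id(self):
        shape = (1, 1, 1)
        data = np.full((2,) + shape, 0.5)
        labels = em_pv.hard_labels(ProbabilityMaps([9, 3], data), phantom_lut().__class__(
            {3: phantom_lut().entries[2], 9: phantom_lut().entries[3]}
        ), np.ones(shape, bool))
        assert labels.data[0, 0, 0] == 3

    def test_pv_correction_reduces_cgm_overestimate(self, pv_em_run):
        truth = pv_em_run["truth"]
        true_cgm = int((truth.truth_labels.data == PHANTOM_CGM_LEFT).sum())
        plain_cgm = int((pv_em_run["labels_plain"].data == PHANTOM_CGM_LEFT).sum())
        pv_cgm = int((pv_em_run["labels_pv"].data == PHANTOM_CGM_LEFT).sum())
        assert plain_cgm > true_cgm  # plain mixture inflates the ribbon
        assert abs(pv_cgm - true_cgm) < abs(plain_cgm - true_cgm)
        assert pv_cgm < plain_cgm

    def test_kappa_continuity_toward_no_pv(self, pv_em_run):
        """kappa -> 0 converges to the segmentation without a PV class."""
        truth = pv_em_run["truth"]
        priors = truth.tissue_priors(2.0)
        pv_priors, pv_id = em_pv.add_pv_class(
            priors, PHANTOM_CGM_LEFT, PHANTOM_WM, kappa=1e-6
        )
        res = em_pv.fit_em_gmm(truth.intensity, pv_priors)
        _, labels = em_pv.merge_pv_into_wm(res, pv_id, PHANTOM_WM, truth.lut, truth.labels.affine)
        plain = pv_em_run["labels_plain"]
        frac_diff = (labels.data != plain.data).mean()
        assert frac_diff < 0.01
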