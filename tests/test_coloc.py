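"""Synthetic image pairs and Mander's colocalization coefficients."""

import numpy as np
import pytest
from dataclasses import replace

from clc4pipe import (
    ImagePair,
    ImageSynthSpec,
    calibrate_overlap_prob,
    manders_overlap,
    oracle_overlap,
    synth_image_pair,
    threshold_channels,
)
from scipy.stats import spearmanr


@pytest.fixture(scope="module")
def clean_spec():
    return ImageSynthSpec(noise_model="none", bg_level=0.0)


class TestSynthesis:
    def test_identical_structures_give_unit_coefficients(self, clean_spec):
        spec = replace(clean_spec, overlap_prob=1.0, n_ch2_only=0)
        pair = synth_image_pair(spec, seed=1)
        t1, t2, masks = threshold_channels(pair)
        res = manders_overlap(pair, masks, thresholds=(t1, t2))
        assert res.overlap_coefficient == pytest.approx(1.0, abs=1e-9)
        assert res.m1 == pytest.approx(1.0) and res.m2 == pytest.approx(1.0)

    def test_disjoint_foregrounds_give_zero(self):
        ch1 = np.zeros((64, 64))
        ch2 = np.zeros((64, 64))
        ch1[10:20, 10:20] = 100.0
        ch2[40:50, 40:50] = 80.0
        pair = ImagePair(ch1=ch1, ch2=ch2)
        t1, t2, masks = threshold_channels(pair, method=(50.0, 40.0))
        res = manders_overlap(pair, masks, thresholds=(t1, t2))
        assert res.overlap_coefficient == 0.0
        assert res.m1 == 0.0 and res.m2 == 0.0

    def test_determinism_and_zero_size_rejected(self, clean_spec):
        a = synth_image_pair(clean_spec, seed=3)
        b = synth_image_pair(clean_spec, seed=3)
        np.testing.assert_array_equal(a.ch1, b.ch1)
        with pytest.raises(ValueError):
            ImageSynthSpec(shape=(0, 64))
        with pytest.raises(ValueError):
            ImageSynthSpec(overlap_prob=1.2)

    def test_measured_equals_oracle_on_ground_truth_channels(self, clean_spec):
        pair = synth_image_pair(replace(clean_spec, overlap_prob=0.6), seed=4)
        masks = (pair.clean_ch1 > 0, pair.clean_ch2 > 0)
        gt_pair = ImagePair(ch1=pair.clean_ch1, ch2=pair.clean_ch2)
        res = manders_overlap(gt_pair, masks)
        assert res.overlap_coefficient == pytest.approx(oracle_overlap(pair),
                                                        abs=1e-9)


class TestThresholding:
    def test_bimodal_image_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        img = np.full((64, 64), 10.0)
        img[:20] = 100.0
        img += rng.normal(0, 1, img.shape)
        pair = ImagePair(ch1=img, ch2=img.copy())
        t1, _, _ = threshold_channels(pair)
        assert 10.5 < t1 < 99.5  # strictly between the two modes

    def test_fixed_thresholds_apply_exactly(self):
        img = np.arange(100.0).reshape(10, 10)
        pair = ImagePair(ch1=img, ch2=img.copy())
        t1, t2, masks = threshold_channels(pair, method=(50.0, 30.0))
        np.testing.assert_array_equal(masks[0], img > 50.0)
        np.testing.assert_array_equal(masks[1], img > 30.0)

    def test_otsu_attains_brute_force_between_class_variance(self):
        """The chosen threshold maximizes the between-class variance computed
        by exhaustive search over the same 256-bin histogram. (The objective
        can be flat across the empty gap between modes, so the *objective* is
        compared, not the tied argmax position.)"""
        rng = np.random.default_rng(1)
        img = np.concatenate([rng.normal(30, 5, 2000),
                              rng.normal(180, 12, 1500)])
        img = np.clip(img, 0, 255).reshape(50, 70)
        pair = ImagePair(ch1=img, ch2=img.copy())
        t1, _, _ = threshold_channels(pair)

        counts, edges = np.histogram(img.ravel(), bins=256)
        mids = 0.5 * (edges[:-1] + edges[1:])
        w = counts / counts.sum()

        def objective(j):
            w0, w1 = w[:j].sum(), w[j:].sum()
            if w0 == 0 or w1 == 0:
                return -np.inf
            mu0 = (w[:j] @ mids[:j]) / w0
            mu1 = (w[j:] @ mids[j:]) / w1
            return w0 * w1 * (mu0 - mu1) ** 2

        best_var = max(objective(j) for j in range(1, 256))
        j_otsu = int(np.searchsorted(mids, t1, side="right"))
        assert objective(j_otsu) >= best_var * (1 - 1e-9)

    def test_constant_image_suggests_fixed_threshold(self):
        pair = ImagePair(ch1=np.ones((8, 8)), ch2=np.ones((8, 8)))
        with pytest.raises(ValueError, match="fixed"):
            threshold_channels(pair)


class TestInvariances:
    def test_scale_invariance_of_coefficients(self, clean_spec):
        pair = synth_image_pair(replace(clean_spec, overlap_prob=0.5), seed=6)
        t1, t2, masks = threshold_channels(pair)
        base = manders_overlap(pair, masks, thresholds=(t1, t2))
        scaled = ImagePair(ch1=7.0 * pair.ch1, ch2=pair.ch2)
        res = manders_overlap(scaled, masks, thresholds=(7.0 * t1, t2))
        assert res.overlap_coefficient == pytest.approx(
            base.overlap_coefficient, rel=1e-12)
        assert res.m1 == pytest.approx(base.m1, rel=1e-12)
        assert res.m2 == pytest.approx(base.m2, rel=1e-12)

    def test_overlap_monotone_in_designed_probability(self, clean_spec):
        probs = np.linspace(0.05, 1.0, 10)
        rs = []
        for p in probs:
            vals = [oracle_overlap(synth_image_pair(
                replace(clean_spec, overlap_prob=p), seed=s))
                for s in range(3)]
            rs.append(np.mean(vals))
        rank_corr = spearmanr(probs, rs).statistic
        assert rank_corr > 0.95

    def test_empty_foreground_flagged(self):
        pair = ImagePair(ch1=np.zeros((8, 8)), ch2=np.zeros((8, 8)))
        masks = (pair.ch1 > 0, pair.ch2 > 0)
        res = manders_overlap(pair, masks)
        assert not res.defined and np.isnan(res.overlap_coefficient)


class TestCalibration:
    def test_bisection_hits_designed_coefficient(self):
        """The mean measured coefficient over a small cohort lands on the
        designed value (single images scatter with sd ~0.06)."""
        spec = ImageSynthSpec()
        p = calibrate_overlap_prob(0.7, spec, seed=9)
        vals = []
        for s in range(8):
            pair = synth_image_pair(
                replace(spec, overlap_prob=p, noise_model="none"),
                seed=123 + s)
            t1, t2, masks = threshold_channels(pair)
            res = manders_overlap(pair, masks, thresholds=(t1, t2))
            vals.append(res.overlap_coefficient)
        assert np.mean(vals) == pytest.approx(0.7, abs=0.05)

    def test_unachievable_target_rejected(self):
        spec = ImageSynthSpec(n_ch2_only=200)
        with pytest.raises(ValueError, match="achievable"):
            calibrate_overlap_prob(0.99, spec, seed=9)
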