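"""Metric oracle checks: every metric against an independent brute-force
reimplementation plus the worked closed-form examples."""

import numpy as np
import pytest
from scipy import stats

from ramanprep.io import Spectrum, ValidationError, WavenumberAxis
from ramanprep.metrics import (
    ClassificationScores,
    DegenerateInputError,
    RegionSpec,
    classification_metrics,
    image_contrast_metrics,
    linf,
    paired_test,
    quantification_error,
    rmse,
    snr_spec,
)

# ---- independent brute-force oracles (loops, no vectorization) -------------


def _rmse_brute(x, y):
    acc = 0.0
    for xi, yi in zip(x, y):
        acc += (yi - xi) ** 2
    return (acc / len(x)) ** 0.5


def _linf_brute(x, y):
    return max(abs(yi - xi) for xi, yi in zip(x, y))


def _auc_brute(pos, neg):
    wins = 0.0
    for m in pos:
        for n in neg:
            if m > n:
                wins += 1.0
            elif m == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _eq_brute(pred, actual):
    import math

    return math.sqrt(sum((math.log10(a) - math.log10(p)) ** 2 for p, a in zip(pred, actual)))


class TestVectorMetrics:
    def test_worked_examples(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
        assert linf([1, 2], [4, 0]) == 3.0
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert linf([5.0], [5.0]) == 0.0

    def test_homogeneity_and_symmetry(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert rmse(3 * x, 3 * y) == pytest.approx(3 * rmse(x, y))
        assert rmse(x, y) == pytest.approx(rmse(y, x))

    @pytest.mark.parametrize("trial", range(100))
    def test_brute_force_equivalence(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(1, 20))
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert abs(rmse(x, y) - _rmse_brute(x, y)) <= 1e-12
        assert abs(linf(x, y) - _linf_brute(x, y)) <= 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rmse([1, 2], [1, 2, 3])


class TestClassification:
    def test_perfect_separation(self):
        rep = classification_metrics(ClassificationScores([0.9, 0.8], [0.1, 0.2]))
        assert rep["auc"] == 1.0

    def test_worked_auc_example(self):
        rep = classification_metrics(ClassificationScores([0.8, 0.4], [0.6, 0.2]))
        assert rep["auc"] == 0.75

    def test_confusion_counts_worked_example(self):
        # TP=3, FN=1, FP=1, TN=3 at threshold 0.5
        scores = ClassificationScores(
            pos_scores=[0.9, 0.8, 0.7, 0.2], neg_scores=[0.1, 0.2, 0.3, 0.6], threshold=0.5
        )
        rep = classification_metrics(scores)
        assert rep["sensitivity"] == 0.75
        assert rep["specificity"] == 0.75
        assert rep["ppv"] == 0.75
        assert rep["npv"] == 0.75

    @pytest.mark.parametrize("trial", range(100))
    def test_auc_brute_force_and_mann_whitney_identity(self, trial):
        rng = np.random.default_rng(200 + trial)
        pos = rng.normal(1, 1, int(rng.integers(2, 10)))
        neg = rng.normal(0, 1, int(rng.integers(2, 10)))
        rep = classification_metrics(ClassificationScores(pos, neg))
        assert abs(rep["auc"] - _auc_brute(pos, neg)) <= 1e-12
        u, _ = stats.mannwhitneyu(pos, neg, alternative="two-sided")
        assert abs(rep["auc"] - u / (len(pos) * len(neg))) <= 1e-12

    def test_empty_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            ClassificationScores([], [0.1])


class TestQuantification:
    def test_one_decade_error_is_one(self):
        assert quantification_error([1e-5], [1e-4]) == pytest.approx(1.0)

    def test_two_samples_each_one_decade_off(self):
        assert quantification_error([1e-5, 1e-6], [1e-4, 1e-7]) == pytest.approx(np.sqrt(2))

    def test_exact_prediction_is_zero(self):
        assert quantification_error([1e-4, 1e-6], [1e-4, 1e-6]) == 0.0

    @pytest.mark.parametrize("trial", range(100))
    def test_brute_force_equivalence(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(1, 8))
        pred = 10.0 ** rng.uniform(-7, -3, n)
        actual = 10.0 ** rng.uniform(-7, -3, n)
        assert abs(quantification_error(pred, actual) - _eq_brute(pred, actual)) <= 1e-12

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            quantification_error([0.0], [1e-4])


class TestSnrSpec:
    def _spectrum(self, sig_val, silent_val):
        ax = np.linspace(400, 3200, 512)
        inten = np.where((ax >= 2800) & (ax < 3200), sig_val,
                         np.where((ax >= 1800) & (ax < 2800), silent_val, 0.0))
        return Spectrum(WavenumberAxis(ax), inten)

    def test_100_to_1_is_20db(self):
        assert snr_spec(self._spectrum(100.0, 1.0)) == pytest.approx(20.0)

    def test_equal_means_is_0db(self):
        assert snr_spec(self._spectrum(5.0, 5.0)) == pytest.approx(0.0)

    def test_zero_silent_zone_is_finite_and_capped(self):
        v = snr_spec(self._spectrum(100.0, 0.0))
        assert np.isfinite(v)
        assert v == 120.0  # cap

    def test_missing_region_rejected(self):
        ax = np.linspace(400, 1800, 256)
        s = Spectrum(WavenumberAxis(ax), np.ones(256))
        with pytest.raises(ValidationError, match="region"):
            snr_spec(s)

    def test_disjoint_region_validation(self):
        with pytest.raises(ValidationError):
            RegionSpec(signal=(2000.0, 3000.0), silent=(1800.0, 2800.0))


class TestImageContrast:
    def _masks(self):
        sig = np.zeros((4, 4), dtype=bool)
        sig[:2] = True
        return sig, ~sig

    def test_worked_cnr_example(self):
        # C_sig = 10, C_bg = 2 (alternating 0/4), sigma_bg = 2 -> CNR = 4
        sig, bg = self._masks()
        raw = np.full((4, 4), 10.0)
        raw[bg] = np.tile([0.0, 4.0], 4)
        rep = image_contrast_metrics(raw, raw, sig, bg)
        assert rep["cnr_raw"] == pytest.approx(4.0)
        assert rep["normalized_cnr"] == pytest.approx(1.0)
        assert rep["normalized_stdb"] == pytest.approx(1.0)

    def test_zero_contrast(self):
        sig, bg = self._masks()
        img = np.full((4, 4), 0.0)
        img[bg] = np.tile([1.0, -1.0], 4)
        img[sig] = 0.0  # equals background mean
        rep = image_contrast_metrics(img, img + np.where(sig, 0, 0.5), sig, bg)
        assert rep["cnr_raw"] == pytest.approx(0.0)

    def test_overlapping_masks_rejected(self):
        sig, _ = self._masks()
        with pytest.raises(ValidationError, match="disjoint"):
            image_contrast_metrics(np.ones((4, 4)), np.ones((4, 4)), sig, sig)

    def test_zero_background_sd_rejected(self):
        sig, bg = self._masks()
        with pytest.raises(DegenerateInputError):
            image_contrast_metrics(np.ones((4, 4)), np.ones((4, 4)), sig, bg)


class TestPairedTests:
    def test_exact_signed_rank_all_positive_n5(self):
        # all 5 differences positive: two-sided exact p = 2/32
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        assert paired_test(a, b, "signed_rank") == pytest.approx(0.0625)

    def test_calibration_under_null(self):
        """Symmetric-noise differences give roughly uniform p-values."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            a = rng.normal(size=30)
            ps.append(paired_test(a + rng.normal(scale=0.5, size=30), a, "signed_rank"))
        ps = np.array(ps)
        assert 0.35 <= np.mean(ps < 0.5) <= 0.65
        assert np.mean(ps < 0.1) <= 0.2

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            paired_test([1, 2, 3], [1, 2], "signed_rank")

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "signed_rank")

    def test_mann_whitney_detects_shift(self, rng):
        a = rng.normal(3, 1, 40)
        b = rng.normal(0, 1, 40)
        assert paired_test(a, b, "mann_whitney") < 1e-6
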