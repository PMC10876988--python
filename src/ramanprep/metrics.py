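"""Evaluation metrics for spectra, classifiers, quantification and images.

Spectral error metrics (RMSE, L-infinity), classification accuracy indexes
(pairwise AUC, sensitivity/specificity/PPV/NPV), log-scale quantification
error, spectral SNR from the C-H / silent regions, masked image
contrast-to-noise metrics, and the nonparametric significance tests used
to compare preprocessing methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ValidationError

__all__ = [
    "ClassificationScores",
    "RegionSpec",
    "MetricReport",
    "DegenerateInputError",
    "rmse",
    "linf",
    "classification_metrics",
    "quantification_error",
    "snr_spec",
    "image_contrast_metrics",
    "paired_test",
]


class DegenerateInputError(ValueError):
    """A metric is undefined on this input (e.g. all-zero paired differences)."""


@dataclass
class ClassificationScores:
    """Prediction scores of true positives and true negatives, with an
    optional decision threshold producing the confusion counts."""

    pos_scores: np.ndarray
    neg_scores: np.ndarray
    threshold: float | None = None

    def __post_init__(self):
        self.pos_scores = np.asarray(self.pos_scores, dtype=np.float64)
        self.neg_scores = np.asarray(self.neg_scores, dtype=np.float64)
        if len(self.pos_scores) < 1 or len(self.neg_scores) < 1:
            raise DegenerateInputError("need at least one positive and one negative score")

    def confusion(self) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) at the stored threshold (score >= threshold -> positive)."""
        if self.threshold is None:
            raise ValidationError("no threshold set")
        tp = int(np.sum(self.pos_scores >= self.threshold))
        fn = len(self.pos_scores) - tp
        fp = int(np.sum(self.neg_scores >= self.threshold))
        tn = len(self.neg_scores) - fp
        return tp, fn, fp, tn


@dataclass(frozen=True)
class RegionSpec:
    """Half-open wavenumber regions used by the spectral SNR: the C-H
    vibration (signal) region and the biologically silent (noise) region."""

    signal: tuple[float, float] = (2800.0, 3200.0)
    silent: tuple[float, float] = (1800.0, 2800.0)

    def __post_init__(self):
        s, n = self.signal, self.silent
        if not (s[0] < s[1] and n[0] < n[1]):
            raise ValidationError("regions must be nonempty intervals")
        if max(s[0], n[0]) < min(s[1], n[1]):
            raise ValidationError("signal and silent regions must be disjoint")


@dataclass
class MetricReport:
    """Named scalar results plus a hash of the inputs they were computed from."""

    values: dict = field(default_factory=dict)
    inputs_hash: str = ""

    def __getitem__(self, k):
        return self.values[k]


def _check_equal_lengths(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValidationError("empty input")
    return x, y


def rmse(x, y) -> float:
    """Root mean squared error between two equal-length vectors."""
    x, y = _check_equal_lengths(x, y)
    return float(np.sqrt(np.mean((y - x) ** 2)))


def linf(x, y) -> float:
    """Maximum absolute deviation between two equal-length vectors."""
    x, y = _check_equal_lengths(x, y)
    return float(np.max(np.abs(y - x)))


def auc_pairwise(pos_scores, neg_scores) -> float:
    """AUC as the fraction of (positive, negative) score pairs ranked
    correctly; ties count one half."""
    pos = np.asarray(pos_scores, dtype=np.float64)[:, None]
    neg = np.asarray(neg_scores, dtype=np.float64)[None, :]
    wins = np.sum(pos > neg) + 0.5 * np.sum(pos == neg)
    return float(wins / (pos.shape[0] * neg.shape[1]))


def classification_metrics(scores: ClassificationScores) -> MetricReport:
    """AUC plus threshold metrics (sensitivity, specificity, PPV, NPV)."""
    values = {"auc": auc_pairwise(scores.pos_scores, scores.neg_scores)}
    if scores.threshold is not None:
        tp, fn, fp, tn = scores.confusion()
        def ratio(a, b):
            if a + b == 0:
                raise DegenerateInputError("confusion ratio with zero denominator")
            return a / (a + b)
        values.update(
            sensitivity=ratio(tp, fn),
            specificity=ratio(tn, fp),
            ppv=ratio(tp, fp),
            npv=ratio(tn, fn),
        )
    return MetricReport(values=values)


def quantification_error(pred, actual) -> float:
    """Quantification error: sqrt of the summed squared log10 differences
    between predicted and actual concentrations (all values > 0)."""
    pred, actual = _check_equal_lengths(pred, actual)
    if np.any(pred <= 0) or np.any(actual <= 0):
        raise ValidationError("concentrations must be positive")
    d = np.log10(actual) - np.log10(pred)
    return float(np.sqrt(np.sum(d * d)))


def snr_spec(spectrum, regions: RegionSpec = RegionSpec(),
             eps_rel: float = 1e-12, cap_db: float = 120.0) -> float:
    """Spectral SNR in dB: mean intensity over the C-H region divided by the
    mean over the silent region, on a log10 scale.

    Both means are floored at ``eps_rel * max|intensity|`` so spectra whose
    silent zone is driven to exactly zero stay finite; the result is capped
    at ``+/- cap_db``.
    """
    axis = spectrum.axis.values
    inten = spectrum.intensity
    out_means = []
    for name, (lo, hi) in (("signal", regions.signal), ("silent", regions.silent)):
        mask = (axis >= lo) & (axis < hi)
        if not np.any(mask):
            raise ValidationError(f"axis does not cover the {name} region [{lo}, {hi})")
        out_means.append(float(np.mean(inten[mask])))
    floor = eps_rel * max(float(np.max(np.abs(inten))), 1e-300)
    sig = max(out_means[0], floor)
    if out_means[1] <= floor:
        # no measurable silent-zone intensity: capped SNR (0 dB if the
        # signal region is empty too)
        return cap_db if out_means[0] > floor else 0.0
    return float(np.clip(10.0 * np.log10(sig / out_means[1]), -cap_db, cap_db))


def image_contrast_metrics(raw_map, pre_map, signal_mask, background_mask) -> MetricReport:
    """Masked contrast-to-noise ratio and background-SD metrics for a raw /
    preprocessed channel-map pair.

    CNR = (mean over signal mask - mean over background mask) / background SD;
    normalized CNR = CNR_raw / CNR_pre; normalized STDB = sigma_bg_raw /
    sigma_bg_pre (both expressed relative to the preprocessed image).
    """
    raw = np.asarray(raw_map, dtype=np.float64)
    pre = np.asarray(pre_map, dtype=np.float64)
    sig = np.asarray(signal_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if raw.shape != pre.shape or raw.shape != sig.shape or raw.shape != bg.shape:
        raise ValidationError("maps and masks must share one shape")
    if not sig.any() or not bg.any():
        raise ValidationError("masks must be nonempty")
    if np.any(sig & bg):
        raise ValidationError("signal and background masks must be disjoint")

    def cnr_stdb(img):
        c_sig = float(np.mean(img[sig]))
        c_bg = float(np.mean(img[bg]))
        s_bg = float(np.std(img[bg]))
        if s_bg == 0:
            raise DegenerateInputError("zero background SD; CNR undefined")
        return (c_sig - c_bg) / s_bg, s_bg

    cnr_r, stdb_r = cnr_stdb(raw)
    cnr_p, stdb_p = cnr_stdb(pre)
    if cnr_p == 0:
        raise DegenerateInputError("preprocessed CNR is zero; normalized CNR undefined")
    return MetricReport(values={
        "cnr_raw": cnr_r,
        "cnr_pre": cnr_p,
        "stdb_raw": stdb_r,
        "stdb_pre": stdb_p,
        "normalized_cnr": cnr_r / cnr_p,
        "normalized_stdb": stdb_r / stdb_p,
    })


def paired_test(a, b, kind: str = "signed_rank") -> float:
    """Two-sided nonparametric comparison of two samples.

    ``signed_rank`` is the Wilcoxon signed-rank test for correlated samples
    (equal lengths required); ``mann_whitney`` the Mann-Whitney U test for
    independent samples.  Exact enumeration is used for small paired
    samples (n <= 12), the normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if kind == "signed_rank":
        if a.shape != b.shape:
            raise ValidationError("signed_rank requires equal-length samples")
        if len(a) < 3:
            raise ValidationError("need n >= 3")
        d = a - b
        if np.all(d == 0):
            raise DegenerateInputError("all paired differences are zero")
        method = "exact" if len(d) <= 12 and not np.any(d == 0) else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                             correction=(method == "approx"))
        return float(res.pvalue)
    if kind == "mann_whitney":
        if len(a) < 3 or len(b) < 3:
            raise ValidationError("need n >= 3 in both samples")
        use_exact = len(a) <= 12 and len(b) <= 12 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if use_exact else "asymptotic")
        return float(res.pvalue)
    raise ValidationError(f"unknown test kind {kind!r}")
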