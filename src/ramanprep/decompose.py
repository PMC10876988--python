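"""Wavelet decomposition of spectra into noise / baseline / signal, and
extraction of isolated peak fragments.

This is the front end of the training-data factory: real (or simulated)
spectra are split by a multilevel discrete wavelet transform -- the finest
detail levels are treated as noise, the approximation plus coarsest details
as baseline, and the middle detail levels as Raman signal.  Individual peaks
are then cut out of the signal component by a first-difference method so
they can later be recombined into new ideal spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .io import Spectrum, ValidationError

__all__ = [
    "SpectrumComponents",
    "PeakFragment",
    "ComponentPools",
    "decompose_spectrum",
    "extract_peak_fragments",
    "build_component_pools",
]

# Level roles for an 8-level split: d1-d2 noise, d3-d6 signal,
# d7-d8 + approximation baseline.
DEFAULT_FAMILY = "db8"
DEFAULT_LEVELS = 8
NOISE_LEVELS = (1, 2)
SIGNAL_LEVELS = (3, 4, 5, 6)


@dataclass
class SpectrumComponents:
    """Additive split of one spectrum: signal + baseline + noise == source."""

    signal: np.ndarray
    baseline: np.ndarray
    noise: np.ndarray
    source: Spectrum


@dataclass
class PeakFragment:
    """One isolated, baseline-free peak profile over [start, end)."""

    start: int
    end: int
    profile: np.ndarray
    apex: int
    source_id: str = ""

    def __post_init__(self):
        if not (self.start < self.apex < self.end):
            raise ValidationError(
                f"fragment apex {self.apex} not inside ({self.start}, {self.end})"
            )
        if len(self.profile) != self.end - self.start:
            raise ValidationError("profile length != end - start")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ComponentPools:
    """Pools of extracted noises, baselines and peak fragments."""

    noises: list = field(default_factory=list)
    baselines: list = field(default_factory=list)
    peaks: list = field(default_factory=list)

    def validate_nonempty(self):
        if not (self.noises and self.baselines and self.peaks):
            raise ValidationError(
                f"pools must be nonempty before assembly "
                f"(noises={len(self.noises)}, baselines={len(self.baselines)}, "
                f"peaks={len(self.peaks)})"
            )


def _reconstruct_levels(coeffs, keep: set[int], length: int, family: str) -> np.ndarray:
    """Inverse DWT keeping only the named components.

    ``coeffs`` is the pywt wavedec list [aJ, dJ, ..., d1]; ``keep`` contains
    detail level numbers (1 = finest) and/or 0 for the approximation.
    """
    levels = len(coeffs) - 1
    sel = [c if (0 in keep if i == 0 else (levels - i + 1) in keep) else np.zeros_like(c)
           for i, c in enumerate(coeffs)]
    rec = pywt.waverec(sel, family, mode="smooth")
    return rec[:length]


def decompose_spectrum(
    s: Spectrum, levels: int = DEFAULT_LEVELS, family: str = DEFAULT_FAMILY
) -> SpectrumComponents:
    """Split a spectrum into noise, baseline, and signal components.

    The three components sum exactly to the input: any wavelet
    reconstruction residual is assigned to the noise component.
    """
    x = s.intensity
    if len(x) < 2**levels:
        raise ValidationError(
            f"spectrum length {len(x)} too short for {levels}-level decomposition"
        )
    coeffs = pywt.wavedec(x, family, level=levels, mode="smooth")
    noise = _reconstruct_levels(coeffs, set(NOISE_LEVELS), len(x), family)
    signal = _reconstruct_levels(coeffs, set(SIGNAL_LEVELS), len(x), family)
    baseline_levels = {0} | {
        lv for lv in range(1, levels + 1) if lv not in NOISE_LEVELS and lv not in SIGNAL_LEVELS
    }
    baseline = _reconstruct_levels(coeffs, baseline_levels, len(x), family)
    noise = noise + (x - (noise + signal + baseline))  # enforce exact partition
    return SpectrumComponents(signal=signal, baseline=baseline, noise=noise, source=s)


def extract_peak_fragments(
    signal: np.ndarray,
    min_prominence: float = 0.02,
    min_width: int = 3,
    source_id: str = "",
) -> list[PeakFragment]:
    """Cut isolated peak fragments out of a (baseline-free) signal vector.

    Candidate apexes are points where the first difference changes sign
    from + to -.  Each fragment extends from its apex to the nearest
    first-difference sign change (local minimum) or sub-threshold point on
    either side.  Fragments narrower than ``min_width`` points or with peak
    prominence below ``min_prominence * max(signal)`` are discarded.  The
    stored profile is the signal over [start, end) minus the linear chord
    between the endpoints, floor-clipped at 0.
    """
    sig = np.asarray(signal, dtype=np.float64)
    if not np.all(np.isfinite(sig)):
        raise ValidationError("signal contains non-finite values")
    n = len(sig)
    if n < 3 or np.all(sig == 0):
        return []
    smax = float(np.max(np.abs(sig)))
    if smax == 0:
        return []
    thresh = min_prominence * smax
    floor = 0.05 * thresh  # sub-threshold boundary cut-off

    d = np.diff(sig)
    apexes = [i for i in range(1, n - 1) if d[i - 1] > 0 and d[i] <= 0]
    fragments = []
    for apex in apexes:
        lo = apex
        while lo > 0 and d[lo - 1] > 0 and sig[lo] > floor:
            lo -= 1
        hi = apex
        while hi < n - 1 and d[hi] <= 0 and sig[hi + 1] > floor:
            hi += 1
        start, end = lo, hi + 1
        if end - start < max(min_width, 3):
            continue
        seg = sig[start:end]
        chord = np.linspace(seg[0], seg[-1], len(seg))
        profile = np.clip(seg - chord, 0.0, None)
        if profile.max() < thresh:
            continue
        rel_apex = int(np.argmax(profile))
        if not (0 < rel_apex < len(profile) - 1):
            continue
        fragments.append(
            PeakFragment(start=start, end=end, profile=profile, apex=start + rel_apex,
                         source_id=source_id)
        )
    fragments.sort(key=lambda f: f.start)
    return fragments


def build_component_pools(
    spectra: list,
    levels: int = DEFAULT_LEVELS,
    family: str = DEFAULT_FAMILY,
    min_prominence: float = 0.02,
    min_width: int = 3,
) -> ComponentPools:
    """Decompose a set of spectra and pool their components.

    One (noise, baseline) entry is stored per input spectrum; all peak
    fragments that survive the prominence/width filters are pooled.
    """
    if not spectra:
        raise ValidationError("need at least one spectrum to build pools")
    pools = ComponentPools()
    for idx, s in enumerate(spectra):
        comps = decompose_spectrum(s, levels=levels, family=family)
        pools.noises.append(comps.noise)
        pools.baselines.append(comps.baseline)
        pools.peaks.extend(
            extract_peak_fragments(
                comps.signal,
                min_prominence=min_prominence,
                min_width=min_width,
                source_id=f"s{idx}",
            )
        )
    return pools
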