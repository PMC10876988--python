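"""Classical preprocessing comparators: iterative polynomial fitting and
wavelet level-selection.

Both operate on a single spectrum, preserve its axis and length, and serve
as the reference methods the learned preprocessor is benchmarked against.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.signal import savgol_filter

from .io import Spectrum, ValidationError

__all__ = ["polynomial_preprocess", "wavelet_preprocess", "wavelet_filter"]


def polynomial_preprocess(
    s: Spectrum,
    order: int = 5,
    max_iter: int = 100,
    window: int = 50,
    tol: float = 0.05,
) -> Spectrum:
    """Iterative polynomial baseline fit followed by local smoothing.

    A polynomial of the given order is fitted; points above the fit are
    replaced by the fit and the fit repeated until the relative L2 change
    of the fitted baseline drops below ``tol`` (5% default) or ``max_iter``
    is reached.  The converged baseline is subtracted, then the residual is
    denoised by local polynomial (Savitzky-Golay) smoothing over a moving
    window of ~``window`` points.
    """
    if order < 1:
        raise ValidationError("polynomial order must be >= 1")
    if window < 3:
        raise ValidationError("smoothing window must be >= 3")
    y = s.intensity
    n = len(y)
    if n <= window:
        raise ValidationError(f"spectrum length {n} not longer than window {window}")
    t = np.linspace(-1.0, 1.0, n)  # scaled abscissa keeps the fit well-conditioned
    work = y.copy()
    prev = None
    for _ in range(max_iter):
        coef = np.polynomial.polynomial.polyfit(t, work, order)
        fit = np.polynomial.polynomial.polyval(t, coef)
        work = np.minimum(work, fit)
        if prev is not None:
            denom = np.linalg.norm(prev)
            if denom == 0 or np.linalg.norm(fit - prev) / denom < tol:
                prev = fit
                break
        prev = fit
    corrected = y - prev
    wl = window + 1 if window % 2 == 0 else window  # savgol needs an odd window
    wl = min(wl, n if n % 2 == 1 else n - 1)
    # polyorder 7 keeps narrow-peak apexes while still averaging noise
    smoothed = savgol_filter(corrected, window_length=wl, polyorder=min(7, wl - 1))
    return Spectrum(s.axis, smoothed, {**s.meta, "preprocess": "polyfit"})


def wavelet_filter(
    x: np.ndarray,
    family: str = "db8",
    levels: int = 8,
    keep: tuple[int, ...] = (3, 4, 5, 6),
    cycles: int = 1,
) -> np.ndarray:
    """Multilevel DWT reconstruction keeping only the given detail levels.

    Levels are numbered from the finest (1).  Levels below the kept band are
    treated as noise, levels above plus the approximation as baseline.  The
    selection is applied ``cycles`` times; being (near-)idempotent it
    stabilizes after the first pass.  Inputs shorter than ``2**levels`` are
    symmetrically padded for the transform and cropped back.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    pad = 0
    if n < 2**levels:
        pad = 2**levels - n
        x = np.pad(x, (0, pad), mode="symmetric")
    out = x
    for _ in range(max(1, cycles)):
        coeffs = pywt.wavedec(out, family, level=levels, mode="smooth")
        sel = [np.zeros_like(coeffs[0])]  # drop approximation (baseline)
        for i, c in enumerate(coeffs[1:], start=1):
            lv = levels - i + 1
            sel.append(c if lv in keep else np.zeros_like(c))
        out = pywt.waverec(sel, family, mode="smooth")[: len(x)]
    return out[:n] if pad else out


def wavelet_preprocess(
    s: Spectrum,
    family: str = "db8",
    levels: int = 8,
    keep: tuple[int, ...] = (3, 4, 5, 6),
    cycles: int = 100,
) -> Spectrum:
    """Wavelet-transform preprocessing of a spectrum (see
    :func:`wavelet_filter`); the 100-cycle default mirrors common practice
    even though pure level selection stabilizes after one cycle."""
    out = wavelet_filter(s.intensity, family=family, levels=levels, keep=keep, cycles=cycles)
    return Spectrum(s.axis, out, {**s.meta, "preprocess": "wavelet"})
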