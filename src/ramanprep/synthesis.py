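"""Training-pair synthesis.

Two generators produce (reference, ideal) spectrum pairs on a fixed grid:

* **recombination** -- ideal spectra are assembled from peak fragments
  extracted from decomposed source spectra (5-20 fragments per spectrum,
  random position and amplitude), then references are built by adding
  pooled noise and baseline components at controlled severity;
* **mathsim** -- the classical mathematical simulation used as an ablation
  control: Lorentzian peaks, i.i.d. Gaussian white noise and a smooth
  random multipoint baseline.

Severity is controlled by a target spectral SNR (dB) and a baseline
amplitude expressed in multiples of the tallest peak.  Both generators are
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .decompose import ComponentPools
from .io import PairCollection, Spectrum, TrainingPair, ValidationError, WavenumberAxis

__all__ = [
    "SynthesisConfig",
    "SEVERITY_PRESETS",
    "assemble_ideal",
    "synthesize_reference",
    "scale_to_target_snr",
    "generate_mathsim_pair",
    "generate_mathsim_sources",
    "build_dataset",
]

SNR_SUPPORTED_RANGE = (-10.0, 60.0)

# Severity regimes for reference synthesis: target-SNR range in dB and
# baseline amplitude range in multiples of the tallest ideal peak.
# "baseline_dominated" mirrors the regime where baselines dwarf the peaks
# while noise stays moderate.
SEVERITY_PRESETS = {
    "default": {"snr_db": (5.0, 40.0), "baseline_rel": (0.0, 5.0)},
    "baseline_dominated": {"snr_db": (10.0, 30.0), "baseline_rel": (1.0, 5.0)},
}


@dataclass
class SynthesisConfig:
    """Configuration for dataset synthesis.

    ``kmin``/``kmax`` bound the number of peaks per ideal spectrum,
    ``amp_jitter`` the multiplicative amplitude range applied to each
    placed fragment.
    """

    n_spectra: int = 10_000
    kmin: int = 5
    kmax: int = 20
    grid_len: int = 1024
    wavenumber_range: tuple[float, float] = (400.0, 1800.0)
    snr_db_range: tuple[float, float] = (5.0, 40.0)
    baseline_rel_range: tuple[float, float] = (0.0, 5.0)
    amp_jitter: tuple[float, float] = (0.5, 1.5)
    # mathsim-only knobs
    lorentz_fwhm_range: tuple[float, float] = (5.0, 50.0)  # cm^-1
    lorentz_amp_range: tuple[float, float] = (0.2, 1.0)
    baseline_control_points: tuple[int, int] = (4, 8)
    seed: int = 0

    def __post_init__(self):
        if self.n_spectra < 1:
            raise ValidationError("n_spectra must be >= 1")
        if not (1 <= self.kmin <= self.kmax):
            raise ValidationError(f"need 1 <= kmin <= kmax, got [{self.kmin}, {self.kmax}]")
        for name in ("snr_db_range", "baseline_rel_range", "amp_jitter"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValidationError(f"invalid range for {name}: ({lo}, {hi})")

    def with_severity(self, preset: str) -> "SynthesisConfig":
        p = SEVERITY_PRESETS[preset]
        return replace(self, snr_db_range=p["snr_db"], baseline_rel_range=p["baseline_rel"])

    def axis(self) -> WavenumberAxis:
        return WavenumberAxis(
            np.linspace(self.wavenumber_range[0], self.wavenumber_range[1], self.grid_len)
        )


def assemble_ideal(
    pools: ComponentPools, cfg: SynthesisConfig, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[list[dict]]]:
    """Assemble ideal (peaks-only, zero-baseline) spectra from a peak pool.

    For each spectrum, k ~ Uniform{kmin..kmax} fragments are drawn with
    replacement, placed at uniformly random start positions (fully inside
    the grid), amplitude-scaled by Uniform(amp_jitter), and summed
    additively.  Returns the spectra and per-spectrum manifests of
    ``{fragment, position, scale}`` records.
    """
    if not pools.peaks:
        raise ValidationError("peak pool is empty")
    L = cfg.grid_len
    usable = [i for i, f in enumerate(pools.peaks) if len(f) <= L]
    if not usable:
        raise ValidationError("every pooled fragment is longer than the grid")
    ideals, manifests = [], []
    for _ in range(cfg.n_spectra):
        k = int(rng.integers(cfg.kmin, cfg.kmax + 1))
        y = np.zeros(L)
        manifest = []
        for _ in range(k):
            fi = usable[int(rng.integers(len(usable)))]
            frag = pools.peaks[fi]
            start = int(rng.integers(0, L - len(frag) + 1))
            scale = float(rng.uniform(*cfg.amp_jitter))
            y[start : start + len(frag)] += scale * frag.profile
            manifest.append({"fragment": fi, "position": start, "scale": scale})
        ideals.append(y)
        manifests.append(manifest)
    return ideals, manifests


def _grid_power(v: np.ndarray) -> float:
    return float(np.mean(np.square(v)))


def scale_to_target_snr(y: np.ndarray, noise: np.ndarray, target_db: float) -> float:
    """Noise coefficient alpha achieving a target spectral SNR.

    Closed form ``alpha = sqrt(P_signal / (P_noise * 10^(target/10)))``
    with powers taken as mean squares over the whole grid.
    """
    if not (SNR_SUPPORTED_RANGE[0] <= target_db <= SNR_SUPPORTED_RANGE[1]):
        raise ValidationError(
            f"target SNR {target_db} dB outside supported range {SNR_SUPPORTED_RANGE}"
        )
    p_sig, p_noise = _grid_power(np.asarray(y)), _grid_power(np.asarray(noise))
    if p_sig == 0 or p_noise == 0:
        raise ValidationError("zero-power signal or noise")
    return float(np.sqrt(p_sig / (p_noise * 10.0 ** (target_db / 10.0))))


def realized_snr_db(y: np.ndarray, scaled_noise: np.ndarray) -> float:
    """Realized SNR in dB: grid mean-square signal power over noise power."""
    p_sig, p_noise = _grid_power(y), _grid_power(scaled_noise)
    if p_noise == 0:
        return float("inf")
    return float(10.0 * np.log10(p_sig / p_noise)) if p_sig > 0 else float("-inf")


def synthesize_reference(
    y: np.ndarray, noise: np.ndarray, baseline: np.ndarray, alpha: float, beta: float
) -> TrainingPair:
    """Build ``x = y + alpha*noise + beta*baseline`` with realized SNR recorded."""
    y = np.asarray(y, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if not (len(y) == len(noise) == len(baseline)):
        raise ValidationError("y, noise, baseline must have equal lengths")
    x = y + alpha * noise + beta * baseline
    return TrainingPair(x=x, y=y, alpha=float(alpha), beta=float(beta),
                        snr_db=realized_snr_db(y, alpha * noise))


def _draw_severity(y, noise_unit, baseline_unit, cfg, rng):
    """Draw (alpha, beta) for one pair from the configured severity ranges."""
    target = float(rng.uniform(*cfg.snr_db_range))
    alpha = scale_to_target_snr(y, noise_unit, target)
    rel = float(rng.uniform(*cfg.baseline_rel_range))
    peak_height = float(np.max(y))
    beta = rel * peak_height
    return alpha, beta


def _lorentzian(axis: np.ndarray, center: float, fwhm: float, amp: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return amp * gamma**2 / ((axis - center) ** 2 + gamma**2)


def _smooth_baseline(L: int, rng: np.random.Generator, n_points: tuple[int, int]) -> np.ndarray:
    """Monotone-cubic interpolation through random control points, unit max."""
    m = int(rng.integers(n_points[0], n_points[1] + 1))
    xs = np.sort(rng.uniform(0, L - 1, size=m))
    xs = np.concatenate([[0.0], xs, [L - 1.0]])
    ys = rng.uniform(0.0, 1.0, size=len(xs))
    b = PchipInterpolator(xs, ys)(np.arange(L))
    mx = np.max(np.abs(b))
    return b / mx if mx > 0 else b


def generate_mathsim_pair(
    cfg: SynthesisConfig, rng: np.random.Generator
) -> tuple[TrainingPair, dict]:
    """One mathematically simulated pair: Lorentzian peaks + Gaussian white
    noise + smooth multipoint baseline.  Returns the pair and a manifest of
    all drawn parameters."""
    axis = cfg.axis().values
    L = cfg.grid_len
    k = int(rng.integers(cfg.kmin, cfg.kmax + 1))
    lo, hi = cfg.wavenumber_range
    margin = 0.02 * (hi - lo)
    y = np.zeros(L)
    peaks = []
    for _ in range(k):
        center = float(rng.uniform(lo + margin, hi - margin))
        fwhm = float(rng.uniform(*cfg.lorentz_fwhm_range))
        amp = float(rng.uniform(*cfg.lorentz_amp_range))
        y += _lorentzian(axis, center, fwhm, amp)
        peaks.append({"center": center, "fwhm": fwhm, "amplitude": amp})
    noise = rng.standard_normal(L)
    baseline = _smooth_baseline(L, rng, cfg.baseline_control_points)
    alpha, beta = _draw_severity(y, noise, baseline, cfg, rng)
    pair = synthesize_reference(y, noise, baseline, alpha, beta)
    manifest = {"peaks": peaks, "alpha": alpha, "beta": beta}
    return pair, manifest


def generate_mathsim_sources(n: int, cfg: SynthesisConfig, rng: np.random.Generator) -> list[Spectrum]:
    """Simulated raw source spectra (reference side of mathsim pairs); these
    stand in for measured source pools when building component pools."""
    axis = cfg.axis()
    out = []
    for _ in range(n):
        pair, _ = generate_mathsim_pair(cfg, rng)
        out.append(Spectrum(axis, pair.x, {"origin": "mathsim"}))
    return out


def build_dataset(
    cfg: SynthesisConfig,
    mode: str = "recombination",
    pools: ComponentPools | None = None,
) -> PairCollection:
    """Build a full training/validation pair collection.

    ``mode`` is ``"recombination"`` (requires ``pools``) or ``"mathsim"``.
    Deterministic given ``cfg.seed``; provenance (mode, seed, sizes) is
    stored on the collection, and per-spectrum peak manifests are attached
    as ``collection.manifests``.
    """
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.axis()
    pairs: list[TrainingPair] = []
    manifests: list = []
    if mode == "recombination":
        if pools is None:
            raise ValidationError("recombination mode requires component pools")
        pools.validate_nonempty()
        ideals, manifests = assemble_ideal(pools, cfg, rng)
        noise_pool = [np.asarray(v) for v in pools.noises if len(v) == cfg.grid_len]
        base_pool = [np.asarray(v) for v in pools.baselines if len(v) == cfg.grid_len]
        if not noise_pool or not base_pool:
            raise ValidationError("noise/baseline pools contain no grid-length entries")
        for y in ideals:
            noise = noise_pool[int(rng.integers(len(noise_pool)))]
            nstd = float(np.std(noise))
            noise_u = noise / nstd if nstd > 0 else noise
            base = base_pool[int(rng.integers(len(base_pool)))]
            bmax = float(np.max(np.abs(base)))
            base_u = base / bmax if bmax > 0 else base
            alpha, beta = _draw_severity(y, noise_u, base_u, cfg, rng)
            pairs.append(synthesize_reference(y, noise_u, base_u, alpha, beta))
    elif mode == "mathsim":
        for _ in range(cfg.n_spectra):
            pair, manifest = generate_mathsim_pair(cfg, rng)
            pairs.append(pair)
            manifests.append(manifest)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    coll = PairCollection(
        axis,
        pairs,
        provenance={
            "mode": mode,
            "seed": cfg.seed,
            "n_spectra": cfg.n_spectra,
            "kmin": cfg.kmin,
            "kmax": cfg.kmax,
            "grid_len": cfg.grid_len,
        },
    )
    coll.manifests = manifests
    return coll
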