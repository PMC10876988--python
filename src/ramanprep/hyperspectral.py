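"""Hyperspectral cube handling: per-pixel preprocessing, quality metrics,
chemical channel maps, PCA feature maps, and a synthetic cube generator.

A cube is an H x W image whose every pixel holds a full spectrum on a
shared wavenumber axis.  Channel maps slice one Raman shift across pixels
(e.g. 2850 cm^-1 CH2 for lipids, 2928 cm^-1 CH3 for proteins/DNA); the
1800-2800 cm^-1 silent zone acts as a noise reference for the spectral
SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from sklearn.decomposition import PCA

from .io import Spectrum, ValidationError, WavenumberAxis
from .metrics import RegionSpec, snr_spec

__all__ = [
    "HyperspectralCube",
    "CubeConfig",
    "read_cube",
    "write_cube",
    "preprocess_cube",
    "top_k_mean_spectrum",
    "channel_map",
    "merge_rgb",
    "pca_feature_maps",
    "simulate_cube",
]

CUBE_FORMAT_VERSION = 1


@dataclass
class HyperspectralCube:
    """H x W x L intensities on a shared axis, with optional masks."""

    axis: WavenumberAxis
    intensities: np.ndarray
    signal_mask: np.ndarray | None = None
    background_mask: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise ValidationError(f"cube must be H x W x L, got shape {arr.shape}")
        if arr.shape[2] != len(self.axis):
            raise ValidationError(
                f"cube spectral length {arr.shape[2]} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("cube contains non-finite intensities")
        self.intensities = arr
        for name in ("signal_mask", "background_mask"):
            m = getattr(self, name)
            if m is not None and np.asarray(m).shape != arr.shape[:2]:
                raise ValidationError(f"{name} shape does not match image shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def pixel(self, i: int, j: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[i, j])

    def pixels_matrix(self) -> np.ndarray:
        H, W, L = self.shape
        return self.intensities.reshape(H * W, L)


def write_cube(cube: HyperspectralCube, path) -> None:
    """HDF5 layout: attrs H, W, format_version; /axis; /pixels (H*W, L)
    row-major; optional /signal_mask, /background_mask."""
    H, W, L = cube.shape
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = CUBE_FORMAT_VERSION
        f.attrs["H"], f.attrs["W"] = H, W
        f.create_dataset("axis", data=cube.axis.values)
        f.create_dataset("pixels", data=cube.pixels_matrix())
        for name in ("signal_mask", "background_mask"):
            m = getattr(cube, name)
            if m is not None:
                f.create_dataset(name, data=np.asarray(m, dtype=bool))


def read_cube(path) -> HyperspectralCube:
    with h5py.File(path, "r") as f:
        H, W = int(f.attrs["H"]), int(f.attrs["W"])
        axis = WavenumberAxis(f["axis"][...])
        pixels = f["pixels"][...]
        if pixels.shape[0] != H * W:
            raise ValidationError(
                f"{path}: header says {H}x{W}={H * W} pixels, file has {pixels.shape[0]}"
            )
        masks = {
            name: (f[name][...] if name in f else None)
            for name in ("signal_mask", "background_mask")
        }
    return HyperspectralCube(axis, pixels.reshape(H, W, -1), **masks)


def preprocess_cube(cube: HyperspectralCube, preprocessor) -> HyperspectralCube:
    """Apply a spectral preprocessor to every pixel independently.

    ``preprocessor`` is anything with ``preprocess_batch(list[Spectrum])``
    (e.g. a trained model) or a callable Spectrum -> Spectrum.  Pixel order
    is row-major and deterministic; the axis is preserved.
    """
    H, W, L = cube.shape
    spectra = [Spectrum(cube.axis, cube.intensities[i, j]) for i in range(H) for j in range(W)]
    if hasattr(preprocessor, "preprocess_batch"):
        done = preprocessor.preprocess_batch(spectra)
    else:
        done = [preprocessor(s) for s in spectra]
    out = np.stack([s.intensity for s in done]).reshape(H, W, L)
    return HyperspectralCube(cube.axis, out, cube.signal_mask, cube.background_mask)


def top_k_mean_spectrum(cube: HyperspectralCube, k: int | None = None,
                        regions: RegionSpec = RegionSpec()) -> Spectrum:
    """Average the k pixel spectra with the highest spectral SNR.

    Default k = min(10 000, H*W) -- the image-level quality summary that
    avoids averaging in blank-substrate pixels.
    """
    H, W, L = cube.shape
    n = H * W
    if k is None:
        k = min(10_000, n)
    if not (1 <= k <= n):
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    mat = cube.pixels_matrix()
    snrs = np.array([snr_spec(Spectrum(cube.axis, mat[i]), regions) for i in range(n)])
    top = np.argsort(snrs, kind="stable")[::-1][:k]
    return Spectrum(cube.axis, mat[top].mean(axis=0), {"top_k": str(k)})


def channel_map(cube: HyperspectralCube, shift: float, band: float = 0.0,
                scale: bool = False) -> np.ndarray:
    """Intensity image at one Raman shift.

    The nearest axis index is used (ties broken toward the lower index);
    with ``band > 0`` the mean over all axis points within +/- band is
    taken.  ``scale=True`` min-max scales the map to [0, 1].
    """
    axis = cube.axis.values
    lo, hi = cube.axis.span
    if not (lo <= shift <= hi):
        raise ValidationError(f"shift {shift} outside axis span [{lo}, {hi}]")
    if band > 0:
        mask = np.abs(axis - shift) <= band
        img = cube.intensities[:, :, mask].mean(axis=2)
    else:
        d = np.abs(axis - shift)
        img = cube.intensities[:, :, int(np.argmin(d))]  # argmin takes the lower index on ties
    if scale:
        img = _minmax(img)
    return img


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img)  # degenerate rule: constant map -> 0
    return (img - lo) / (hi - lo)


def merge_rgb(red: np.ndarray, green: np.ndarray, blue: np.ndarray) -> np.ndarray:
    """Stack three channel maps into an H x W x 3 color image, each channel
    min-max scaled independently (argument order R, G, B)."""
    maps = [np.asarray(m, dtype=np.float64) for m in (red, green, blue)]
    if not (maps[0].shape == maps[1].shape == maps[2].shape):
        raise ValidationError("channel maps must share one shape")
    return np.stack([_minmax(m) for m in maps], axis=-1)


def pca_feature_maps(cube: HyperspectralCube, n_components: int = 3):
    """PCA across pixels (observations) and wavenumbers (variables).

    Returns (maps, explained_variance_ratio): component-score images
    min-max scaled to [0, 1], variance ratios non-increasing.
    """
    H, W, L = cube.shape
    if n_components > L:
        raise ValidationError(f"n_components {n_components} exceeds spectral length {L}")
    if H * W < n_components:
        raise ValidationError("fewer pixels than requested components")
    mat = cube.pixels_matrix()
    if np.allclose(mat, mat[0]):
        raise ValidationError("degenerate cube: all pixels identical")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(mat)  # centers internally
    maps = [_minmax(scores[:, c].reshape(H, W)) for c in range(n_components)]
    return maps, pca.explained_variance_ratio_


@dataclass
class CubeConfig:
    """Synthetic cell-image cube: elliptical regions carrying distinct C-H
    peak sets on a smooth baseline field with Gaussian noise."""

    height: int = 32
    width: int = 32
    grid_len: int = 512
    wavenumber_range: tuple[float, float] = (400.0, 3200.0)
    n_cells: int = 3
    noise_sd: float = 0.02
    baseline_amp: float = 0.5
    peak_height: float = 1.0

    def axis(self) -> WavenumberAxis:
        return WavenumberAxis(
            np.linspace(self.wavenumber_range[0], self.wavenumber_range[1], self.grid_len)
        )


def _gauss_peak(axis, center, fwhm, amp):
    sd = fwhm / 2.3548200450309493
    return amp * np.exp(-0.5 * ((axis - center) / sd) ** 2)


def simulate_cube(cfg: CubeConfig, rng: np.random.Generator) -> HyperspectralCube:
    """Deterministic-by-seed synthetic cube with ground-truth masks.

    Alternating elliptical "cells" are lipid-like (2850 cm^-1 CH2 dominant)
    or protein-like (2928 cm^-1 CH3 dominant), each with a few fingerprint
    bands; the background carries only baseline and noise.  The silent
    zone stays peak-free, so the spectral SNR contrast between cells and
    background is known by construction.
    """
    axis = cfg.axis()
    av = axis.values
    H, W, L = cfg.height, cfg.width, cfg.grid_len
    cells = np.zeros((H, W), dtype=bool)
    kind = np.zeros((H, W), dtype=int)
    ii, jj = np.mgrid[0:H, 0:W]
    for c in range(cfg.n_cells):
        cy, cx = rng.uniform(0.2, 0.8) * H, rng.uniform(0.2, 0.8) * W
        ry, rx = rng.uniform(0.1, 0.2) * H, rng.uniform(0.1, 0.2) * W
        inside = ((ii - cy) / ry) ** 2 + ((jj - cx) / rx) ** 2 <= 1.0
        cells |= inside
        kind[inside] = c % 2 + 1

    lipid = _gauss_peak(av, 2850.0, 40.0, 1.0) + _gauss_peak(av, 1451.0, 25.0, 0.5)
    protein = _gauss_peak(av, 2928.0, 40.0, 1.0) + _gauss_peak(av, 1658.0, 25.0, 0.5)
    base_shape = np.exp(-((av - 400.0) / 1500.0))  # smooth monotone fluorescence-like decay

    cube = np.empty((H, W, L))
    for i in range(H):
        for j in range(W):
            y = np.zeros(L)
            if kind[i, j] == 1:
                y = cfg.peak_height * lipid
            elif kind[i, j] == 2:
                y = cfg.peak_height * protein
            b = cfg.baseline_amp * float(rng.uniform(0.5, 1.5)) * base_shape
            noise = cfg.noise_sd * rng.standard_normal(L)
            cube[i, j] = y + (b + noise if (cfg.baseline_amp > 0 or cfg.noise_sd > 0) else 0.0)
    return HyperspectralCube(axis, cube, signal_mask=cells, background_mask=~cells)
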