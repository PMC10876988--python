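"""Spectrum containers and file I/O.

Spectra are plain two-column delimited text (Raman shift in cm^-1,
intensity in counts); pair collections (reference/ideal training pairs on a
shared axis) live in a small, versioned HDF5 layout.  Everything downstream
works on a fixed-length wavenumber grid, so resampling utilities live here
too.

Indices are 0-based and intervals half-open throughout the package.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "TrainingPair",
    "PairCollection",
    "SpectrumParseError",
    "ValidationError",
    "read_spectrum",
    "write_spectrum",
    "resample_to_grid",
    "read_pairs",
    "write_pairs",
]

PAIR_FORMAT_VERSION = 1


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed (carries the offending line number)."""


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


def _as_float_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=np.float64)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm^-1 (length >= 8)."""

    values: np.ndarray

    def __post_init__(self):
        vals = _as_float_vector(self.values, "axis")
        if len(vals) < 8:
            raise ValidationError(f"axis needs >= 8 points, got {len(vals)}")
        if not np.all(np.diff(vals) > 0):
            raise ValidationError("axis must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


@dataclass
class Spectrum:
    """A single spectrum: intensity counts on a wavenumber axis."""

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.axis, WavenumberAxis):
            self.axis = WavenumberAxis(np.asarray(self.axis))
        self.intensity = _as_float_vector(self.intensity, "intensity")
        if len(self.intensity) != len(self.axis):
            raise ValidationError(
                f"intensity length {len(self.intensity)} != axis length {len(self.axis)}"
            )

    def __len__(self) -> int:
        return len(self.axis)


@dataclass
class TrainingPair:
    """Reference spectrum ``x`` with its ideal (peaks-only) label ``y``.

    ``x = y + alpha*noise + beta*baseline`` for synthesized pairs; the
    realized spectral SNR in dB is recorded.
    """

    x: np.ndarray
    y: np.ndarray
    alpha: float = 0.0
    beta: float = 0.0
    snr_db: float = float("nan")

    def __post_init__(self):
        self.x = _as_float_vector(self.x, "x")
        self.y = _as_float_vector(self.y, "y")
        if len(self.x) != len(self.y):
            raise ValidationError(f"pair length mismatch: {len(self.x)} vs {len(self.y)}")


@dataclass
class PairCollection:
    """Training pairs sharing one wavenumber axis, with provenance."""

    axis: WavenumberAxis
    pairs: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.pairs:
            raise ValidationError("pair collection must be nonempty")
        L = len(self.axis)
        for i, p in enumerate(self.pairs):
            if len(p.x) != L:
                raise ValidationError(f"pair {i} length {len(p.x)} != axis length {L}")

    def __len__(self) -> int:
        return len(self.pairs)

    def x_matrix(self) -> np.ndarray:
        return np.stack([p.x for p in self.pairs])

    def y_matrix(self) -> np.ndarray:
        return np.stack([p.y for p in self.pairs])

    def config_hash(self) -> str:
        blob = repr(sorted(self.provenance.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_DELIMS = re.compile(r"[,\t;]|\s+")


def read_spectrum(path, dialect: str | None = None) -> Spectrum:
    """Read a 2+ column delimited text spectrum.

    Comma/tab/semicolon/whitespace delimiters are auto-detected unless
    ``dialect`` gives an explicit delimiter.  Lines starting with ``#`` are
    comments; rows are sorted by wavenumber (stable).  Duplicated
    wavenumbers and non-finite values are rejected.
    """
    rows = []
    meta = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*[:=]\s*(.*)", line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            parts = (
                line.split(dialect) if dialect else [p for p in _DELIMS.split(line) if p]
            )
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected >=2 columns, got {line!r}")
            try:
                w, i = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: malformed number in {line!r}") from exc
            if not (np.isfinite(w) and np.isfinite(i)):
                raise ValidationError(f"{path}:{lineno}: non-finite value in {line!r}")
            rows.append((w, i))
    if len(rows) < 8:
        raise ValidationError(f"{path}: need >= 8 data rows, got {len(rows)}")
    rows.sort(key=lambda r: r[0])
    w = np.array([r[0] for r in rows])
    i = np.array([r[1] for r in rows])
    if np.any(np.diff(w) == 0):
        raise ValidationError(f"{path}: duplicated wavenumbers")
    return Spectrum(WavenumberAxis(w), i, meta)


def write_spectrum(s: Spectrum, path) -> None:
    """Write a spectrum as 2-column text; meta goes into '#' header lines."""
    with open(path, "w") as fh:
        for k, v in s.meta.items():
            fh.write(f"# {k}: {v}\n")
        for w, i in zip(s.axis.values, s.intensity):
            # repr of a Python float: shortest exact round-trip form
            fh.write(f"{float(w)!r} {float(i)!r}\n")


def resample_to_grid(s: Spectrum, grid_len: int, range_: tuple[float, float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a fixed grid on ``[lo, hi]``.

    Out-of-range grid points take the nearest edge value.  The original
    axis span is recorded in ``meta['original_range']`` so callers can map
    results back.  Idempotent on its own output.
    """
    lo, hi = float(range_[0]), float(range_[1])
    if grid_len < 8:
        raise ValidationError("grid_len must be >= 8")
    s_lo, s_hi = s.axis.span
    if hi <= s_lo or lo >= s_hi:
        raise ValidationError(
            f"requested range [{lo}, {hi}] does not overlap spectrum span [{s_lo}, {s_hi}]"
        )
    grid = np.linspace(lo, hi, grid_len)
    out = np.interp(grid, s.axis.values, s.intensity)  # np.interp edge-fills
    meta = dict(s.meta)
    meta.setdefault("original_range", f"{s_lo},{s_hi}")
    return Spectrum(WavenumberAxis(grid), out, meta)


def write_pairs(collection: PairCollection, path) -> None:
    """Serialize a pair collection to the versioned HDF5 layout.

    Layout: ``/axis`` (L,), ``/x`` (n, L), ``/y`` (n, L), ``/coeffs``
    (n, 3: alpha, beta, snr_db), ``/meta`` attrs with provenance strings.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = PAIR_FORMAT_VERSION
        f.create_dataset("axis", data=collection.axis.values)
        f.create_dataset("x", data=collection.x_matrix())
        f.create_dataset("y", data=collection.y_matrix())
        coeffs = np.array([[p.alpha, p.beta, p.snr_db] for p in collection.pairs])
        f.create_dataset("coeffs", data=coeffs)
        g = f.create_group("meta")
        for k, v in collection.provenance.items():
            g.attrs[str(k)] = str(v)


def read_pairs(path) -> PairCollection:
    """Read a pair collection written by :func:`write_pairs` (lossless)."""
    with h5py.File(path, "r") as f:
        axis = WavenumberAxis(f["axis"][...])
        x = f["x"][...]
        y = f["y"][...]
        coeffs = f["coeffs"][...]
        if x.shape != y.shape or x.shape[0] != coeffs.shape[0]:
            raise ValidationError(f"{path}: inconsistent dataset shapes")
        prov = {k: f["meta"].attrs[k] for k in f["meta"].attrs}
    pairs = [
        TrainingPair(x[i], y[i], float(coeffs[i, 0]), float(coeffs[i, 1]), float(coeffs[i, 2]))
        for i in range(x.shape[0])
    ]
    return PairCollection(axis, pairs, prov)
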