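"""The learned spectral preprocessor.

Architecture: a raw spectrum is fed in parallel to

* a **patches branch** -- the spectrum is split into overlapping sliding
  windows, each window passes through a shared affine map, and windows are
  reassembled by overlap-averaging (initialized to the identity), then a
  three-layer convolutional pre-encoder;
* a **background-estimation branch** -- a small U-shaped network (three
  convolution / three transposed-convolution pairs) that fits the noise +
  baseline contour B(x), followed by its own three-layer pre-encoder.

The pre-encoded feature maps are subtracted (peak features minus background
features) and passed through an Inception-style encoder--decoder: a Stem
that divides the length by 4 while multiplying channels by 4, three
dimension-preserving Inception blocks with two Reduction stages (length
halved, channels doubled) between them, and a symmetric transposed-
convolution upsampling stack with skip connections that restores the input
length.  The output P(x) is the denoised, baseline-corrected spectrum.

Training is two-step: first the background branch alone against the known
background x - y (Huber loss), then the full model with the weighted loss
``lambda * Huber(P(x) - y) + (1 - lambda) * Huber(B(x) - (x - y))``.
Spectra are max-normalized per spectrum on the way in and the scale is
inverted on the way out.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .io import PairCollection, Spectrum, ValidationError, WavenumberAxis
from .nn import Adam, Conv1d, ConvTranspose1d, Module, ReLU, Sequential, huber
from .nn.core import DTYPE, Parameter

__all__ = [
    "PatchesConfig",
    "ModelConfig",
    "TrainedPreprocessor",
    "make_patches",
    "overlap_average",
    "loss_background",
    "loss_total",
    "train_model",
    "estimate_background",
    "forward_preprocess",
    "preprocess",
    "DESK_PRESET",
    "FULL_PRESET",
]


# --------------------------------------------------------------------------
# Patches
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class PatchesConfig:
    """Sliding-window parameters: window (stride length) and step size."""

    window: int = 64
    step: int = 32

    def __post_init__(self):
        if not (1 <= self.step <= self.window):
            raise ValidationError(f"need 1 <= step <= window, got {self}")

    def padded_len(self, L: int) -> int:
        if self.window > L:
            raise ValidationError(f"window {self.window} exceeds length {L}")
        n_steps = math.ceil((L - self.window) / self.step)
        return self.window + n_steps * self.step

    def n_patches(self, L: int) -> int:
        return (self.padded_len(L) - self.window) // self.step + 1


def make_patches(x: np.ndarray, cfg: PatchesConfig) -> np.ndarray:
    """Split a vector into overlapping windows (n_patches x window).

    Patch i covers ``[i*step, i*step + window)``.  The right edge is
    replication-padded so the last window fits exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    Lp = cfg.padded_len(len(x))
    if Lp > len(x):
        x = np.concatenate([x, np.full(Lp - len(x), x[-1])])
    win = np.lib.stride_tricks.sliding_window_view(x, cfg.window)
    return win[:: cfg.step].copy()


def overlap_average(patches: np.ndarray, L: int, cfg: PatchesConfig) -> np.ndarray:
    """Inverse of :func:`make_patches`: average overlapping windows back
    into a length-``L`` vector (exact partition-of-unity reconstruction)."""
    Lp = cfg.padded_len(L)
    acc = np.zeros(Lp)
    counts = np.zeros(Lp)
    for p, patch in enumerate(patches):
        s = p * cfg.step
        acc[s : s + cfg.window] += patch
        counts[s : s + cfg.window] += 1
    return (acc / counts)[:L]


class PatchLinear(Module):
    """Shared per-window affine map with overlap-average reassembly.

    Initialized to the identity, so the branch starts as a pass-through.
    Input/output shape (N, L, 1).
    """

    def __init__(self, cfg: PatchesConfig, L: int):
        self.cfg = cfg
        self.L = L
        self.Lp = cfg.padded_len(L)
        self.W = Parameter(np.eye(cfg.window, dtype=DTYPE))
        self.b = Parameter(np.zeros(cfg.window, dtype=DTYPE))
        counts = np.zeros(self.Lp, dtype=DTYPE)
        for p in range(cfg.n_patches(L)):
            counts[p * cfg.step : p * cfg.step + cfg.window] += 1
        self._counts = counts
        self._cache = None

    def _patchify(self, x2):  # x2: (N, Lp)
        win = np.lib.stride_tricks.sliding_window_view(x2, self.cfg.window, axis=1)
        return np.ascontiguousarray(win[:, :: self.cfg.step])  # (N, P, w)

    def forward(self, x):
        N = x.shape[0]
        x2 = x[:, :, 0]
        if self.Lp > self.L:
            x2 = np.concatenate([x2, np.repeat(x2[:, -1:], self.Lp - self.L, axis=1)], axis=1)
        patches = self._patchify(x2)
        z = patches @ self.W.value.T + self.b.value
        ypad = np.zeros((N, self.Lp), dtype=DTYPE)
        w, st = self.cfg.window, self.cfg.step
        for p in range(z.shape[1]):
            ypad[:, p * st : p * st + w] += z[:, p, :]
        ypad /= self._counts
        self._cache = patches
        return ypad[:, : self.L, None]

    def backward(self, gy):
        patches = self._cache
        N = gy.shape[0]
        w, st = self.cfg.window, self.cfg.step
        gypad = np.zeros((N, self.Lp), dtype=DTYPE)
        gypad[:, : self.L] = gy[:, :, 0]
        gypad /= self._counts
        P = patches.shape[1]
        gz = np.empty((N, P, w), dtype=DTYPE)
        for p in range(P):
            gz[:, p, :] = gypad[:, p * st : p * st + w]
        self.W.grad += np.einsum("npo,npw->ow", gz, patches, optimize=True)
        self.b.grad += gz.sum(axis=(0, 1))
        gpatch = gz @ self.W.value
        gxpad = np.zeros((N, self.Lp), dtype=DTYPE)
        for p in range(P):
            gxpad[:, p * st : p * st + w] += gpatch[:, p, :]
        gx = gxpad[:, : self.L].copy()
        if self.Lp > self.L:
            gx[:, -1] += gxpad[:, self.L :].sum(axis=1)
        return gx[:, :, None]


# --------------------------------------------------------------------------
# Network building blocks
# --------------------------------------------------------------------------
class InceptionBlock(Module):
    """Dimension-preserving multi-kernel block with a residual connection.

    Parallel same-length convolution branches (kernel sizes 1, 3, 7 by
    default) whose output channels concatenate back to the input width; the
    input is added on top.
    """

    KERNELS = (1, 3, 7)

    def __init__(self, channels: int, rng):
        widths = [channels // 2, channels // 4]
        widths.append(channels - sum(widths))
        self.widths = widths
        self.branches = [
            Sequential(Conv1d(channels, w, k, pad=(k - 1) // 2, rng=rng), ReLU())
            for w, k in zip(widths, self.KERNELS)
        ]

    def forward(self, x):
        return np.concatenate([br.forward(x) for br in self.branches], axis=2) + x

    def backward(self, gy):
        gx = gy.copy()
        c0 = 0
        for w, br in zip(self.widths, self.branches):
            gx += br.backward(gy[:, :, c0 : c0 + w])
            c0 += w
        return gx


class BackgroundEstimator(Module):
    """U-shaped contour extractor: three stride-2 convolutions down, three
    transposed convolutions up; final layer zero-initialized so the
    untrained estimate is exactly zero."""

    def __init__(self, rng, widths=(8, 16, 32)):
        w1, w2, w3 = widths
        self.body = Sequential(
            Conv1d(1, w1, 5, stride=2, pad=2, rng=rng), ReLU(),
            Conv1d(w1, w2, 5, stride=2, pad=2, rng=rng), ReLU(),
            Conv1d(w2, w3, 5, stride=2, pad=2, rng=rng), ReLU(),
            ConvTranspose1d(w3, w2, 4, stride=2, pad=1, rng=rng), ReLU(),
            ConvTranspose1d(w2, w1, 4, stride=2, pad=1, rng=rng), ReLU(),
            ConvTranspose1d(w1, 1, 4, stride=2, pad=1, rng=rng, zero_init=True),
        )

    def forward(self, x):
        return self.body.forward(x)

    def backward(self, gy):
        return self.body.backward(gy)


def _pre_encoder(c: int, rng) -> Sequential:
    """Three convolutional layers bringing a 1-channel map to width ``c``."""
    return Sequential(
        Conv1d(1, c, 3, pad=1, rng=rng), ReLU(),
        Conv1d(c, c, 3, pad=1, rng=rng), ReLU(),
        Conv1d(c, c, 3, pad=1, rng=rng),
    )


# --------------------------------------------------------------------------
# Full model
# --------------------------------------------------------------------------
DESK_PRESET = dict(base_channels=8, epochs_be=15, epochs_full=110, lr=2e-3, batch=32)
FULL_PRESET = dict(base_channels=16, epochs_be=100, epochs_full=400, lr=1e-3, batch=64)


@dataclass
class ModelConfig:
    """Hyperparameters of the preprocessing model.

    ``lambda_weight`` balances the reconstruction term against the
    background-estimation term in the total loss (0.2 default); the grid
    length must be divisible by 16 (Stem /4, two Reductions /2 each).
    """

    grid_len: int = 1024
    base_channels: int = 4
    lambda_weight: float = 0.2
    huber_delta: float = 1.0
    epochs_be: int = 20
    epochs_full: int = 50
    lr: float = 1e-3
    batch: int = 32
    seed: int = 0
    patches: PatchesConfig = field(default_factory=PatchesConfig)
    be_widths: tuple[int, int, int] = (8, 16, 32)

    def __post_init__(self):
        if not (0.0 <= self.lambda_weight <= 1.0):
            raise ValidationError("lambda_weight must be in [0, 1]")
        if self.grid_len % 16 != 0:
            raise ValidationError("grid length must be divisible by 16")
        if isinstance(self.patches, dict):
            self.patches = PatchesConfig(**self.patches)

    @classmethod
    def preset(cls, name: str, **overrides) -> "ModelConfig":
        base = {"desk": DESK_PRESET, "full": FULL_PRESET}[name]
        return cls(**{**base, **overrides})


class SpectralPreprocessor(Module):
    """The complete two-branch network; exposes per-stage shape traces."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        c = cfg.base_channels
        L = cfg.grid_len
        self.be = BackgroundEstimator(rng, cfg.be_widths)
        self.patch = PatchLinear(cfg.patches, L)
        self.pre_p = _pre_encoder(c, rng)
        self.pre_b = _pre_encoder(c, rng)
        self.stem = Conv1d(c, 4 * c, 8, stride=4, pad=2, rng=rng)
        self.relu_stem = ReLU()
        self.inc_a = InceptionBlock(4 * c, rng)
        self.red_a = Conv1d(4 * c, 8 * c, 4, stride=2, pad=1, rng=rng)
        self.relu_ra = ReLU()
        self.inc_b = InceptionBlock(8 * c, rng)
        self.red_b = Conv1d(8 * c, 16 * c, 4, stride=2, pad=1, rng=rng)
        self.relu_rb = ReLU()
        self.inc_c = InceptionBlock(16 * c, rng)
        self.up1 = ConvTranspose1d(16 * c, 8 * c, 4, stride=2, pad=1, rng=rng)
        self.relu_u1 = ReLU()
        self.up2 = ConvTranspose1d(8 * c, 4 * c, 4, stride=2, pad=1, rng=rng)
        self.relu_u2 = ReLU()
        self.up3 = ConvTranspose1d(4 * c, c, 8, stride=4, pad=2, rng=rng)
        self.relu_u3 = ReLU()
        # two-layer full-resolution head: peak amplitudes live here
        self.final = Sequential(
            Conv1d(c, c, 5, pad=2, rng=rng), ReLU(), Conv1d(c, 1, 3, pad=1, rng=rng)
        )
        self._cache = None

    # -- forward ---------------------------------------------------------
    def forward_full(self, x, want_trace: bool = False):
        """x: (N, L, 1) -> (B(x), P(x)) both (N, L, 1); optional stage trace
        of (stage name, channels, length)."""
        b_raw = self.be.forward(x)
        patch_out = self.patch.forward(x)
        f_p = self.pre_p.forward(patch_out)
        f_b = self.pre_b.forward(b_raw)
        h = f_p - f_b
        s = self.relu_stem.forward(self.stem.forward(h))
        a = self.inc_a.forward(s)
        ra = self.relu_ra.forward(self.red_a.forward(a))
        bb = self.inc_b.forward(ra)
        rb = self.relu_rb.forward(self.red_b.forward(bb))
        cc = self.inc_c.forward(rb)
        u1 = self.relu_u1.forward(self.up1.forward(cc) + bb)
        u2 = self.relu_u2.forward(self.up2.forward(u1) + a)
        u3 = self.relu_u3.forward(self.up3.forward(u2) + h)
        # global residual: the trunk learns a correction on top of the
        # spectrum-space subtraction (reassembled patches minus background)
        p = self.final.forward(u3) + (patch_out - b_raw)
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(b_raw))):
            raise FloatingPointError("non-finite activations in forward pass")
        self._cache = True
        if want_trace:
            trace = [
                ("stem", s.shape[2], s.shape[1]),
                ("inception_a", a.shape[2], a.shape[1]),
                ("reduction_a", ra.shape[2], ra.shape[1]),
                ("inception_b", bb.shape[2], bb.shape[1]),
                ("reduction_b", rb.shape[2], rb.shape[1]),
                ("inception_c", cc.shape[2], cc.shape[1]),
                ("up_1", u1.shape[2], u1.shape[1]),
                ("up_2", u2.shape[2], u2.shape[1]),
                ("up_3", u3.shape[2], u3.shape[1]),
                ("output", p.shape[2], p.shape[1]),
            ]
            return b_raw, p, trace
        return b_raw, p

    def backward_full(self, g_p, g_b_direct):
        """Backprop given dLoss/dP and the direct dLoss/dB contribution."""
        g = self.final.backward(g_p)
        gz3 = self.relu_u3.backward(g)
        g_h_skip = gz3.copy()
        g = self.up3.backward(gz3)
        gz2 = self.relu_u2.backward(g)
        g_u1 = self.up2.backward(gz2)
        g_a = gz2.copy()
        gz1 = self.relu_u1.backward(g_u1)
        g_cc = self.up1.backward(gz1)
        g_bb = gz1.copy()
        g_rb = self.inc_c.backward(g_cc)
        g_bb += self.red_b.backward(self.relu_rb.backward(g_rb))
        g_ra = self.inc_b.backward(g_bb)
        g_a += self.red_a.backward(self.relu_ra.backward(g_ra))
        g_s = self.inc_a.backward(g_a)
        g_h = self.stem.backward(self.relu_stem.backward(g_s)) + g_h_skip
        self.patch.backward(self.pre_p.backward(g_h) + g_p)
        g_b_total = self.pre_b.backward(-g_h) - g_p + g_b_direct
        self.be.backward(g_b_total)

    def param_hash(self) -> str:
        h = hashlib.sha256()
        for a in self.state_arrays():
            h.update(a.tobytes())
        return h.hexdigest()[:12]


# --------------------------------------------------------------------------
# Losses (public, vector-level contracts)
# --------------------------------------------------------------------------
def _huber_value(r: np.ndarray, delta: float) -> float:
    absr = np.abs(r)
    return float(np.mean(np.where(absr < delta, 0.5 * r * r, delta * (absr - 0.5 * delta))))


def loss_background(x, y, bx, delta: float = 1.0) -> float:
    """Background-estimation loss: mean Huber of ``B(x) - (x - y)``."""
    x, y, bx = (np.asarray(v, dtype=np.float64) for v in (x, y, bx))
    if not (x.shape == y.shape == bx.shape):
        raise ValidationError("x, y, B(x) must share one shape")
    return _huber_value(bx - (x - y), delta)


def loss_total(x, y, bx, px, lam: float = 0.2, delta: float = 1.0) -> float:
    """Total training loss: ``lam * mean Huber(P(x) - y) + (1 - lam) * L_BE``."""
    if not (0.0 <= lam <= 1.0):
        raise ValidationError("lambda must be in [0, 1]")
    px, y2 = np.asarray(px, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if px.shape != y2.shape:
        raise ValidationError("P(x) and y must share one shape")
    return lam * _huber_value(px - y2, delta) + (1.0 - lam) * loss_background(x, y, bx, delta)


# --------------------------------------------------------------------------
# Training and inference
# --------------------------------------------------------------------------
@dataclass
class TrainedPreprocessor:
    """A trained model plus everything needed to apply and reload it."""

    net: SpectralPreprocessor
    config: ModelConfig
    axis: WavenumberAxis
    losses: dict = field(default_factory=dict)
    normalization: str = "per-spectrum max-abs"

    def save(self, path):
        cfg = asdict(self.config)
        cfg["patches"] = asdict(self.config.patches)
        arrays = {f"param_{i}": a for i, a in enumerate(self.net.state_arrays())}
        with open(path, "wb") as fh:  # file handle keeps the exact path (no .npz suffixing)
            np.savez(
                fh,
                config_json=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
                axis=self.axis.values,
                losses_json=np.frombuffer(json.dumps(self.losses).encode(), dtype=np.uint8),
                **arrays,
            )

    @classmethod
    def load(cls, path) -> "TrainedPreprocessor":
        with np.load(path if isinstance(path, _io.IOBase) else str(path)) as z:
            cfg_d = json.loads(bytes(z["config_json"]).decode())
            cfg_d["patches"] = PatchesConfig(**cfg_d["patches"])
            cfg_d["be_widths"] = tuple(cfg_d["be_widths"])
            cfg = ModelConfig(**cfg_d)
            net = SpectralPreprocessor(cfg, np.random.default_rng(cfg.seed))
            n_params = len(net.parameters())
            net.load_state_arrays([z[f"param_{i}"] for i in range(n_params)])
            losses = json.loads(bytes(z["losses_json"]).decode())
            axis = WavenumberAxis(z["axis"])
        return cls(net=net, config=cfg, axis=axis, losses=losses)

    # -- application ------------------------------------------------------
    def _grid_apply(self, X: np.ndarray) -> np.ndarray:
        """Preprocess spectra already on the model grid ((n, L) -> (n, L))."""
        scales = np.maximum(np.max(np.abs(X), axis=1), 1e-12)
        out = np.empty_like(X, dtype=np.float64)
        bs = max(1, self.config.batch)
        for i0 in range(0, X.shape[0], bs):
            xb = (X[i0 : i0 + bs] / scales[i0 : i0 + bs, None]).astype(DTYPE)[:, :, None]
            _, p = self.net.forward_full(xb)
            out[i0 : i0 + bs] = p[:, :, 0].astype(np.float64) * scales[i0 : i0 + bs, None]
        return out

    def preprocess(self, s: Spectrum) -> Spectrum:
        return self.preprocess_batch([s])[0]

    def preprocess_batch(self, spectra: list) -> list:
        """Preprocess spectra on arbitrary axes; output stays on each input's
        native axis (internal resampling to the model grid and back)."""
        grid = self.axis.values
        L = self.config.grid_len
        X = np.empty((len(spectra), L))
        for i, s in enumerate(spectra):
            X[i] = np.interp(grid, s.axis.values, s.intensity)
        P = self._grid_apply(X)
        out = []
        for i, s in enumerate(spectra):
            native = np.interp(s.axis.values, grid, P[i])
            meta = {**s.meta, "model_hash": self.net.param_hash(),
                    "normalization": self.normalization}
            out.append(Spectrum(s.axis, native, meta))
        return out


def estimate_background(x: np.ndarray, model: TrainedPreprocessor | SpectralPreprocessor) -> np.ndarray:
    """B(x): the background-branch output for one grid-length vector."""
    net = model.net if isinstance(model, TrainedPreprocessor) else model
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) != net.cfg.grid_len:
        raise ValidationError(f"expected a length-{net.cfg.grid_len} vector")
    b = net.be.forward(x.astype(DTYPE)[None, :, None])
    return b[0, :, 0].astype(np.float64)


def forward_preprocess(x: np.ndarray, model: TrainedPreprocessor | SpectralPreprocessor,
                       want_trace: bool = False):
    """P(x) for one grid-length vector; optionally the stage shape trace."""
    net = model.net if isinstance(model, TrainedPreprocessor) else model
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) != net.cfg.grid_len:
        raise ValidationError(f"expected a length-{net.cfg.grid_len} vector")
    res = net.forward_full(x.astype(DTYPE)[None, :, None], want_trace=want_trace)
    if want_trace:
        _, p, trace = res
        return p[0, :, 0].astype(np.float64), trace
    _, p = res
    return p[0, :, 0].astype(np.float64)


def _normalize_pairs(pairs: PairCollection):
    X = pairs.x_matrix()
    Y = pairs.y_matrix()
    scales = np.maximum(np.max(np.abs(X), axis=1), 1e-12)
    return (X / scales[:, None]).astype(DTYPE), (Y / scales[:, None]).astype(DTYPE)


def train_model(pairs: PairCollection, cfg: ModelConfig,
                log=None) -> TrainedPreprocessor:
    """Two-step training of the preprocessing model.

    Step 1 trains only the background-estimation branch with the Huber loss
    against the known background ``x - y``; step 2 trains the whole network
    with the lambda-weighted double loss.  Deterministic given ``cfg.seed``
    (single-threaded).  Raises with diagnostics if the loss diverges.
    """
    if len(pairs) < 2 * cfg.batch:
        raise ValidationError(
            f"need at least 2*batch = {2 * cfg.batch} pairs, got {len(pairs)}"
        )
    if len(pairs.axis) != cfg.grid_len:
        raise ValidationError(
            f"pairs are on a length-{len(pairs.axis)} grid, model wants {cfg.grid_len}"
        )
    rng = np.random.default_rng(cfg.seed)
    net = SpectralPreprocessor(cfg, rng)
    Xn, Yn = _normalize_pairs(pairs)
    BG = Xn - Yn
    n = Xn.shape[0]
    delta = cfg.huber_delta
    curves = {"be": [], "full": [], "full_recon": [], "full_be": []}

    def check(loss, phase, epoch):
        if not np.isfinite(loss):
            raise FloatingPointError(f"divergence: non-finite {phase} loss at epoch {epoch}")

    def lr_at(epoch, total):
        # step decay ending in a fine-convergence tail
        if epoch >= int(0.92 * total):
            return cfg.lr * 0.1
        if epoch >= int(0.8 * total):
            return cfg.lr * 0.25
        if epoch >= int(0.5 * total):
            return cfg.lr * 0.5
        return cfg.lr

    opt_be = Adam(net.be.parameters(), lr=cfg.lr)
    for epoch in range(cfg.epochs_be):
        opt_be.lr = lr_at(epoch, cfg.epochs_be)
        order = rng.permutation(n)
        tot = 0.0
        for i0 in range(0, n, cfg.batch):
            idx = order[i0 : i0 + cfg.batch]
            xb = Xn[idx][:, :, None]
            bg = BG[idx][:, :, None]
            net.zero_grad()
            b_out = net.be.forward(xb)
            lval, g = huber(b_out, bg, delta)
            net.be.backward(g)
            opt_be.step()
            tot += lval * len(idx)
        curves["be"].append(tot / n)
        check(curves["be"][-1], "background", epoch)
        if log:
            log(f"[be] epoch {epoch + 1}/{cfg.epochs_be} loss {curves['be'][-1]:.6f}")

    lam = cfg.lambda_weight
    opt = Adam(net.parameters(), lr=cfg.lr)
    for epoch in range(cfg.epochs_full):
        opt.lr = lr_at(epoch, cfg.epochs_full)
        order = rng.permutation(n)
        tot = tot_r = tot_b = 0.0
        for i0 in range(0, n, cfg.batch):
            idx = order[i0 : i0 + cfg.batch]
            xb = Xn[idx][:, :, None]
            yb = Yn[idx][:, :, None]
            bg = BG[idx][:, :, None]
            net.zero_grad()
            b_out, p_out = net.forward_full(xb)
            l_rec, g_p = huber(p_out, yb, delta)
            l_be, g_b = huber(b_out, bg, delta)
            net.backward_full(lam * g_p, (1.0 - lam) * g_b)
            opt.step()
            lval = lam * l_rec + (1.0 - lam) * l_be
            tot += lval * len(idx)
            tot_r += l_rec * len(idx)
            tot_b += l_be * len(idx)
        curves["full"].append(tot / n)
        curves["full_recon"].append(tot_r / n)
        curves["full_be"].append(tot_b / n)
        check(curves["full"][-1], "full", epoch)
        if log:
            log(f"[full] epoch {epoch + 1}/{cfg.epochs_full} loss {curves['full'][-1]:.6f} "
                f"(recon {tot_r / n:.6f}, be {tot_b / n:.6f})")

    return TrainedPreprocessor(net=net, config=cfg, axis=pairs.axis, losses=curves)


def preprocess(s: Spectrum, model: TrainedPreprocessor) -> Spectrum:
    """Preprocess one spectrum on its native axis (function-style wrapper)."""
    return model.preprocess(s)
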