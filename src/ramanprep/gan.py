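"""Adversarial refinement of synthetic reference spectra.

A conditional generator receives an ideal (peaks-only) spectrum together
with a Gaussian latent channel and produces a simulative reference
spectrum; a residual 1D classifier tries to tell generated references from
the recombination-synthesized ones.  Labels are never touched: each
generated spectrum stays paired with the ideal spectrum that conditioned
it.

The generator is three U-shaped 1D blocks on top of a stem convolution,
with a global skip from the ideal-spectrum channel, so it learns to *add*
noise and background onto the ideal spectrum.  Training uses the
non-saturating binary cross-entropy adversarial loss plus an L1
consistency term (weight 10) anchoring outputs to the paired synthetic
reference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .io import PairCollection, TrainingPair, ValidationError, WavenumberAxis
from .nn import Adam, Conv1d, ConvTranspose1d, GlobalAvgPool, Linear, Module, ReLU, Sequential, bce_with_logits
from .nn.core import DTYPE

__all__ = ["GanConfig", "GanCheckpoint", "GanDivergenceError", "gan_train", "gan_generate"]

L1_WEIGHT = 10.0


class GanDivergenceError(RuntimeError):
    """Raised when an adversarial loss goes non-finite; carries the last
    finite checkpoint in ``.checkpoint``."""

    def __init__(self, msg, checkpoint=None):
        super().__init__(msg)
        self.checkpoint = checkpoint


@dataclass
class GanConfig:
    """Desk-scale defaults: small widths, short schedules."""

    grid_len: int = 1024
    latent_len: int | None = None  # defaults to grid_len
    width: int = 8
    epochs: int = 10
    batch: int = 16
    lr: float = 2e-4
    seed: int = 0

    def __post_init__(self):
        if self.latent_len is None:
            self.latent_len = self.grid_len
        if self.latent_len > self.grid_len:
            raise ValidationError("latent_len cannot exceed grid length")
        if self.grid_len % 4 != 0:
            raise ValidationError("grid length must be divisible by 4")
        if min(self.width, self.epochs, self.batch) < 1 or self.lr <= 0:
            raise ValidationError("positive sizes required")


class UBlock(Module):
    """Down/up convolution pair with a residual connection (length kept)."""

    def __init__(self, c, rng):
        self.down = Conv1d(c, 2 * c, 4, stride=2, pad=1, rng=rng)
        self.r1 = ReLU()
        self.up = ConvTranspose1d(2 * c, c, 4, stride=2, pad=1, rng=rng)
        self.r2 = ReLU()

    def forward(self, x):
        return self.r2.forward(self.up.forward(self.r1.forward(self.down.forward(x)))) + x

    def backward(self, gy):
        return self.down.backward(self.r1.backward(self.up.backward(self.r2.backward(gy)))) + gy


class Generator(Module):
    """(ideal, latent) channel-last input (N, L, 2) -> reference spectrum
    = ideal + learned noise/background field."""

    def __init__(self, cfg: GanConfig, rng):
        w = cfg.width
        self.stem = Conv1d(2, w, 3, pad=1, rng=rng)
        self.relu = ReLU()
        self.blocks = [UBlock(w, rng) for _ in range(3)]
        self.final = Conv1d(w, 1, 3, pad=1, rng=rng)

    def forward(self, yz):
        h = self.relu.forward(self.stem.forward(yz))
        for b in self.blocks:
            h = b.forward(h)
        return self.final.forward(h) + yz[:, :, :1]

    def backward(self, gy):
        g = self.final.backward(gy)
        for b in reversed(self.blocks):
            g = b.backward(g)
        g = self.stem.backward(self.relu.backward(g))
        g[:, :, :1] += gy
        return g


class Discriminator(Module):
    """Residual 1D conv classifier -> real/fake logit."""

    def __init__(self, cfg: GanConfig, rng):
        w = cfg.width
        self.front = Sequential(
            Conv1d(1, w, 4, stride=2, pad=1, rng=rng), ReLU(),
            Conv1d(w, 2 * w, 4, stride=2, pad=1, rng=rng), ReLU(),
        )
        self.res = Conv1d(2 * w, 2 * w, 3, pad=1, rng=rng)
        self.res_relu = ReLU()
        self.pool = GlobalAvgPool()
        self.head = Linear(2 * w, 1, rng=rng)

    def forward(self, x):
        h = self.front.forward(x)
        h = self.res_relu.forward(self.res.forward(h)) + h
        return self.head.forward(self.pool.forward(h))

    def backward(self, gy):
        g = self.pool.backward(self.head.backward(gy))
        g = self.res.backward(self.res_relu.backward(g)) + g
        return self.front.backward(g)


@dataclass
class GanCheckpoint:
    generator: Generator
    discriminator: Discriminator
    config: GanConfig
    curves: dict = field(default_factory=dict)

    def save(self, path):
        arrays = {f"g_{i}": a for i, a in enumerate(self.generator.state_arrays())}
        arrays.update({f"d_{i}": a for i, a in enumerate(self.discriminator.state_arrays())})
        with open(path, "wb") as fh:  # exact path (np.savez would append .npz)
            np.savez(fh,
                     config_json=np.frombuffer(json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
                     curves_json=np.frombuffer(json.dumps(self.curves).encode(), dtype=np.uint8),
                     **arrays)

    @classmethod
    def load(cls, path) -> "GanCheckpoint":
        with np.load(str(path)) as z:
            cfg = GanConfig(**json.loads(bytes(z["config_json"]).decode()))
            rng = np.random.default_rng(cfg.seed)
            gen = Generator(cfg, rng)
            disc = Discriminator(cfg, rng)
            gen.load_state_arrays([z[f"g_{i}"] for i in range(len(gen.parameters()))])
            disc.load_state_arrays([z[f"d_{i}"] for i in range(len(disc.parameters()))])
            curves = json.loads(bytes(z["curves_json"]).decode())
        return cls(gen, disc, cfg, curves)


def _latent(rng, n, L, latent_len):
    z = np.zeros((n, L, 1), dtype=DTYPE)
    z[:, :latent_len, 0] = rng.standard_normal((n, latent_len))
    return z


def gan_train(pairs: PairCollection, cfg: GanConfig, log=None) -> GanCheckpoint:
    """Alternating generator/discriminator training on synthesized pairs.

    Reference spectra are max-normalized per pair (the same convention the
    preprocessor uses); the generator sees the correspondingly scaled ideal
    spectrum.  Deterministic under a fixed seed, single-threaded.
    """
    n = len(pairs)
    if cfg.batch > n:
        raise ValidationError(f"batch {cfg.batch} exceeds n_pairs {n}")
    if n < 2 * cfg.batch:
        raise ValidationError(f"need >= 2*batch = {2 * cfg.batch} pairs, got {n}")
    if len(pairs.axis) != cfg.grid_len:
        raise ValidationError("pair grid does not match config grid_len")
    rng = np.random.default_rng(cfg.seed)
    gen = Generator(cfg, rng)
    disc = Discriminator(cfg, rng)
    X = pairs.x_matrix()
    Y = pairs.y_matrix()
    scales = np.maximum(np.max(np.abs(X), axis=1), 1e-12)
    Xn = (X / scales[:, None]).astype(DTYPE)
    Yn = (Y / scales[:, None]).astype(DTYPE)
    opt_g = Adam(gen.parameters(), lr=cfg.lr, beta1=0.5)
    opt_d = Adam(disc.parameters(), lr=cfg.lr, beta1=0.5)
    curves = {"g": [], "d": []}
    ckpt = GanCheckpoint(gen, disc, cfg, curves)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        g_tot = d_tot = 0.0
        nb = 0
        for i0 in range(0, n - cfg.batch + 1, cfg.batch):
            idx = order[i0 : i0 + cfg.batch]
            yb = Yn[idx][:, :, None]
            xb = Xn[idx][:, :, None]
            z = _latent(rng, len(idx), cfg.grid_len, cfg.latent_len)
            yz = np.concatenate([yb, z], axis=2)

            # discriminator step
            fake = gen.forward(yz)
            disc.zero_grad()
            l_real, g_real = bce_with_logits(disc.forward(xb), 1.0)
            disc.backward(g_real)
            l_fake, g_fake = bce_with_logits(disc.forward(fake), 0.0)
            disc.backward(g_fake)
            opt_d.step()
            d_loss = l_real + l_fake

            # generator step (non-saturating + L1 consistency)
            gen.zero_grad()
            fake = gen.forward(yz)
            logit = disc.forward(fake)
            l_adv, g_logit = bce_with_logits(logit, 1.0)
            g_fake_from_d = disc.backward(g_logit)
            r = fake - xb
            l_l1 = float(np.mean(np.abs(r)))
            g_l1 = (np.sign(r) / r.size).astype(DTYPE)
            gen.backward(g_fake_from_d + L1_WEIGHT * g_l1)
            opt_g.step()
            g_loss = l_adv + L1_WEIGHT * l_l1

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise GanDivergenceError(
                    f"non-finite adversarial loss at epoch {epoch}", checkpoint=ckpt
                )
            d_tot += d_loss
            g_tot += g_loss
            nb += 1
        curves["d"].append(d_tot / nb)
        curves["g"].append(g_tot / nb)
        if log:
            log(f"[gan] epoch {epoch + 1}/{cfg.epochs} G {curves['g'][-1]:.4f} D {curves['d'][-1]:.4f}")
    return ckpt


def gan_generate(ckpt: GanCheckpoint, ideals: list, n_per_ideal: int = 1,
                 seed: int = 0, axis: WavenumberAxis | None = None) -> PairCollection:
    """Generate ``n_per_ideal`` refined references per conditioning ideal.

    Each output pair is (generator(y, z_k), y): the label passes through
    bitwise untouched.  Different seeds give different latent draws and
    hence different references for the same ideal.
    """
    cfg = ckpt.config
    rng = np.random.default_rng(seed)
    pairs = []
    for y in ideals:
        y = np.asarray(y, dtype=np.float64)
        if len(y) != cfg.grid_len:
            raise ValidationError(
                f"ideal length {len(y)} does not match checkpoint grid {cfg.grid_len}"
            )
        scale = max(float(np.max(np.abs(y))), 1e-12)
        yb = np.repeat((y / scale).astype(DTYPE)[None, :, None], n_per_ideal, axis=0)
        z = _latent(rng, n_per_ideal, cfg.grid_len, cfg.latent_len)
        fake = ckpt.generator.forward(np.concatenate([yb, z], axis=2))
        for k in range(n_per_ideal):
            x = fake[k, :, 0].astype(np.float64) * scale
            pairs.append(TrainingPair(x=x, y=y, alpha=float("nan"), beta=float("nan"),
                                      snr_db=float("nan")))
    if axis is None:
        axis = WavenumberAxis(np.linspace(0.0, 1.0 * (cfg.grid_len - 1), cfg.grid_len))
    return PairCollection(axis, pairs, provenance={"mode": "gan", "seed": seed,
                                                   "n_per_ideal": n_per_ideal})
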