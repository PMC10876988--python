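"""Layers, losses and the Adam optimizer.

Conventions: activations are float32 arrays shaped channel-last (batch,
length, channels) -- the layout that keeps every convolution a single
contiguous matrix product on one CPU core; every layer caches what its
backward pass needs and accumulates parameter gradients in
``Parameter.grad``.  All random initialization draws from a
caller-supplied :class:`numpy.random.Generator`, so models are
bit-reproducible under a fixed seed on one machine.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base class: parameter collection plus forward/backward protocol."""

    def parameters(self) -> list[Parameter]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    # --- flat (de)serialization -------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value = np.asarray(a, dtype=DTYPE)
            p.grad = np.zeros_like(p.value)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


def _im2col(xp_t: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, Lp, C) channel-last input -> contiguous (N, Lout, C*k) columns."""
    win = np.lib.stride_tricks.sliding_window_view(xp_t, k, axis=1)  # (N, Lp-k+1, C, k)
    win = win[:, ::stride]
    N, Lout, C, _ = win.shape
    return np.ascontiguousarray(win).reshape(N, Lout, C * k)


class Conv1d(Module):
    """1D convolution (cross-correlation), weight (cout, cin, k).

    Channel-last throughout: one contiguous im2col copy, then the whole
    pass is a single sgemm.
    """

    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None, bias=True, zero_init=False):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        if zero_init:
            w = np.zeros((cout, cin, k), dtype=DTYPE)
        else:
            w = he_init(rng, (cout, cin, k), cin * k)
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None
        self._cache = None

    def out_len(self, L: int) -> int:
        return (L + 2 * self.pad - self.k) // self.stride + 1

    def _wmat(self):
        # (C*k, Cout) with (c, k) flattened to match im2col column order
        return self.W.value.transpose(1, 2, 0).reshape(self.cin * self.k, self.cout)

    def forward(self, x):
        N, L, C = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        cols = _im2col(x, self.k, self.stride)  # (N, Lout, C*k)
        y = cols @ self._wmat()  # (N, Lout, Cout)
        if self.b is not None:
            y += self.b.value
        self._cache = (cols, (N, L, C))
        return y

    def backward(self, gy):
        cols, (N, L, C) = self._cache
        Lout = gy.shape[1]
        gy = np.ascontiguousarray(gy, dtype=DTYPE)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 1))
        gy2 = gy.reshape(N * Lout, self.cout)
        cols2 = cols.reshape(N * Lout, C * self.k)
        gw = (cols2.T @ gy2).reshape(C, self.k, self.cout)
        self.W.grad += gw.transpose(2, 0, 1)
        gcols = (gy2 @ self._wmat().T).reshape(N, Lout, C, self.k)
        Lp = L + 2 * self.pad
        gx = np.zeros((N, Lp, C), dtype=DTYPE)
        for kk in range(self.k):
            gx[:, kk : kk + self.stride * Lout : self.stride] += gcols[:, :, :, kk]
        return gx[:, self.pad : self.pad + L] if self.pad else gx


class ConvTranspose1d(Module):
    """1D transposed convolution, weight (cin, cout, k).

    Output length is ``(L - 1) * stride - 2 * pad + k`` (the exact adjoint
    of :class:`Conv1d` with the same k/stride/pad).
    """

    def __init__(self, cin, cout, k, stride=1, pad=0, rng=None, bias=True, zero_init=False):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        if zero_init:
            w = np.zeros((cin, cout, k), dtype=DTYPE)
        else:
            w = he_init(rng, (cin, cout, k), cin * k)
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None
        self._cache = None

    def out_len(self, L: int) -> int:
        return (L - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x):
        N, L, C = x.shape
        Lfull = (L - 1) * self.stride + self.k
        # one gemm producing all kernel-offset contributions, then scatter
        contrib = (x.reshape(N * L, C) @ self.W.value.reshape(C, self.cout * self.k)).reshape(
            N, L, self.cout, self.k
        )
        y = np.zeros((N, Lfull, self.cout), dtype=DTYPE)
        for kk in range(self.k):
            y[:, kk : kk + self.stride * L : self.stride] += contrib[:, :, :, kk]
        if self.pad:
            y = y[:, self.pad : Lfull - self.pad]
        if self.b is not None:
            y = y + self.b.value
        self._cache = (x, Lfull)
        return y

    def backward(self, gy):
        x, Lfull = self._cache
        N, L, C = x.shape
        gy = np.ascontiguousarray(gy, dtype=DTYPE)
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 1))
        if self.pad:
            full = np.zeros((N, Lfull, self.cout), dtype=DTYPE)
            full[:, self.pad : Lfull - self.pad] = gy
            gy = full
        # gather the strided windows back into (N, L, Cout, k)
        gwin = np.empty((N, L, self.cout, self.k), dtype=DTYPE)
        for kk in range(self.k):
            gwin[:, :, :, kk] = gy[:, kk : kk + self.stride * L : self.stride]
        gwin2 = gwin.reshape(N * L, self.cout * self.k)
        x2 = x.reshape(N * L, C)
        self.W.grad += (x2.T @ gwin2).reshape(self.W.value.shape)
        return (gwin2 @ self.W.value.reshape(C, self.cout * self.k).T).reshape(N, L, C)


class Linear(Module):
    def __init__(self, fin, fout, rng=None, zero_init=False):
        w = np.zeros((fout, fin), dtype=DTYPE) if zero_init else he_init(rng, (fout, fin), fin)
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(fout, dtype=DTYPE))
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, gy):
        gy = np.asarray(gy, dtype=DTYPE)
        self.W.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class GlobalAvgPool(Module):
    """(N, L, C) -> (N, C) mean over length."""

    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, gy):
        N, L, C = self._shape
        return np.broadcast_to(gy[:, None, :] / L, self._shape).astype(DTYPE)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def huber(pred: np.ndarray, target: np.ndarray, delta: float = 1.0):
    """Mean Huber loss and its gradient w.r.t. ``pred``.

    Elementwise: 0.5*r^2 for |r| < delta, delta*(|r| - 0.5*delta) otherwise.
    """
    r = pred - target
    absr = np.abs(r)
    quad = absr < delta
    vals = np.where(quad, 0.5 * r * r, delta * (absr - 0.5 * delta))
    grad = np.where(quad, r, delta * np.sign(r)) / r.size
    return float(vals.mean()), grad.astype(DTYPE)


def bce_with_logits(logits: np.ndarray, target: float | np.ndarray):
    """Mean binary cross-entropy on logits; returns (loss, grad_logits)."""
    t = np.broadcast_to(np.asarray(target, dtype=np.float64), logits.shape)
    z = np.asarray(logits, dtype=np.float64)
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = ((sig - t) / z.size).astype(DTYPE)
    return float(loss), grad


class Adam:
    """Adam with the usual bias correction; operates on a fixed parameter list."""

    def __init__(self, params: list[Parameter], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
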