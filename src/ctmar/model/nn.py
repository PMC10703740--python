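"""Minimal convolutional-network machinery in numpy.

Layers operate on single images shaped ``(channels, H, W)`` (the training
scheme uses batch size 1 throughout).  Every layer exposes

    y, cache = layer.forward(x)
    gx = layer.backward(cache, gy)

with parameter gradients *accumulated* into ``layer.grads`` — explicit
caches make it safe to run a module several times inside one objective
(cycle and identity passes reuse the generators) and back-propagate each
pass independently.  All arithmetic follows the input dtype: float32 for
training, float64 for finite-difference gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Module", "Conv2d", "ReflectionPad2d", "InstanceNorm2d", "ReLU",
    "LeakyReLU", "Tanh", "UpsampleNearest2x", "Sequential", "Residual",
    "Adam", "collect_params",
]


class Module:
    """Base layer: parameter/grad dicts plus forward/backward protocol."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, cache, gy):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def modules(self):
        yield self


class Conv2d(Module):
    """2-D convolution (cross-correlation) with zero padding, via im2col."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 init_std: float = 0.02, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride, self.pad = \
            cin, cout, k, stride, pad
        w = rng.normal(0.0, init_std, size=(cout, cin * k * k))
        self.params = {"w": w.astype(dtype), "b": np.zeros(cout, dtype=dtype)}
        self.grads = {"w": np.zeros_like(self.params["w"]),
                      "b": np.zeros_like(self.params["b"])}

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        c, hp, wp = xp.shape
        s = self.stride
        sc, sh, sw = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, shape=(c, self.k, self.k, ho, wo),
            strides=(sc, sh, sw, sh * s, sw * s), writeable=False)
        return view.reshape(c * self.k * self.k, ho * wo)

    def forward(self, x: np.ndarray):
        c, h, w = x.shape
        p, k, s = self.pad, self.k, self.stride
        if p:
            xp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=x.dtype)
            xp[:, p:-p, p:-p] = x
        else:
            xp = x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = np.ascontiguousarray(self._im2col(xp, ho, wo))
        y = self.params["w"] @ cols + self.params["b"][:, None]
        return y.reshape(self.cout, ho, wo), (x.shape, cols, ho, wo)

    def backward(self, cache, gy: np.ndarray):
        (c, h, w), cols, ho, wo = cache
        p, k, s = self.pad, self.k, self.stride
        g2 = gy.reshape(self.cout, -1)
        self.grads["w"] += g2 @ cols.T
        self.grads["b"] += g2.sum(axis=1)
        dcols = (self.params["w"].T @ g2).reshape(c, k, k, ho, wo)
        gxp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=gy.dtype)
        for ki in range(k):
            for kj in range(k):
                gxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s] += dcols[:, ki, kj]
        return gxp[:, p:p + h, p:p + w] if p else gxp


class ReflectionPad2d(Module):
    def __init__(self, pad: int) -> None:
        super().__init__()
        self.pad = pad

    @staticmethod
    def _idx(n: int, p: int) -> np.ndarray:
        idx = np.arange(-p, n + p)
        idx = np.abs(idx)                      # reflect at 0
        idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)  # reflect at n-1
        return idx

    def forward(self, x: np.ndarray):
        p = self.pad
        ir = self._idx(x.shape[1], p)
        ic = self._idx(x.shape[2], p)
        return x[:, ir[:, None], ic[None, :]], (x.shape, ir, ic)

    def backward(self, cache, gy: np.ndarray):
        shape, ir, ic = cache
        gx = np.zeros(shape, dtype=gy.dtype)
        np.add.at(gx, (slice(None), ir[:, None], ic[None, :]), gy)
        return gx


class InstanceNorm2d(Module):
    """Per-channel spatial normalization (no affine parameters)."""

    def __init__(self, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps

    def forward(self, x: np.ndarray):
        mean = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        return xhat, (xhat, inv)

    def backward(self, cache, gy: np.ndarray):
        xhat, inv = cache
        m1 = gy.mean(axis=(1, 2), keepdims=True)
        m2 = (gy * xhat).mean(axis=(1, 2), keepdims=True)
        return inv * (gy - m1 - xhat * m2)


class ReLU(Module):
    def forward(self, x):
        m = x > 0
        return x * m, m

    def backward(self, cache, gy):
        return gy * cache


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x):
        m = x > 0
        return np.where(m, x, self.slope * x), m

    def backward(self, cache, gy):
        return np.where(cache, gy, self.slope * gy)


class Tanh(Module):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, cache, gy):
        return gy * (1.0 - cache * cache)


class UpsampleNearest2x(Module):
    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2), x.shape

    def backward(self, cache, gy):
        c, h, w = cache
        return gy.reshape(c, h, 2, w, 2).sum(axis=(2, 4))


class Sequential(Module):
    def __init__(self, layers: list[Module]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, gy):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            gy = layer.backward(c, gy)
        return gy

    def modules(self):
        for layer in self.layers:
            yield from layer.modules()


class Residual(Module):
    """y = x + f(x); f must preserve shape."""

    def __init__(self, body: Sequential) -> None:
        super().__init__()
        self.body = body

    def forward(self, x):
        y, c = self.body.forward(x)
        return x + y, c

    def backward(self, cache, gy):
        return gy + self.body.backward(cache, gy)

    def modules(self):
        yield from self.body.modules()


def collect_params(root: Module) -> list[tuple[Module, str]]:
    """Flat list of (module, parameter-name) pairs under ``root``."""
    out = []
    for m in root.modules():
        for name in m.params:
            out.append((m, name))
    return out


class Adam:
    """Adam optimizer over a list of (module, name) parameter handles."""

    def __init__(self, handles: list[tuple[Module, str]], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.handles = handles
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(mod.params[n]) for mod, n in handles]
        self.v = [np.zeros_like(mod.params[n]) for mod, n in handles]

    def zero_grad(self) -> None:
        for mod, n in self.handles:
            mod.grads[n][...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (mod, n) in enumerate(self.handles):
            g = mod.grads[n]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            mod.params[n] -= (self.lr * mhat /
                              (np.sqrt(vhat) + self.eps)).astype(
                                  mod.params[n].dtype)
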