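"""Minimal numpy neural-network engine.

Every layer implements a pure ``forward(x) -> (y, cache)`` and a
``backward(dy, cache) -> dx`` that accumulates parameter gradients in-place.
Caches are explicit so a layer can be applied several times per step (the
recurrent gate networks are shared across time) without state clashes.

All arrays are float64: the engine is sized for desk-scale experiments and
finite-difference gradient verification, not GPU throughput.
"""

from __future__ import annotations

import hashlib
from typing import Callable, Iterator

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Module",
    "Dense",
    "Conv1d",
    "ReLU",
    "Sigmoid",
    "Tanh",
    "GlobalMaxPool1d",
    "TemporalMaxPool",
    "Sequential",
    "MLP",
    "Adam",
    "softmax",
    "sigmoid",
    "fan_in_uniform",
    "finite_difference_grad",
    "params_hash",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Weight init: U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: owns ``params``/``grads`` dicts and named children."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.children: dict[str, "Module"] = {}

    def add_child(self, name: str, module: "Module") -> "Module":
        self.children[name] = module
        return module

    def named_params(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, arr in self.params.items():
            yield f"{prefix}{name}", arr
        for cname, child in self.children.items():
            yield from child.named_params(prefix=f"{prefix}{cname}/")

    def named_grads(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, arr in self.grads.items():
            yield f"{prefix}{name}", arr
        for cname, child in self.children.items():
            yield from child.named_grads(prefix=f"{prefix}{cname}/")

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0
        for child in self.children.values():
            child.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_params())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for key, arr in own.items():
            new = np.asarray(state[key], dtype=float)
            if new.shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}: expected {arr.shape}, got {new.shape}")
            arr[...] = new

    def forward(self, x: np.ndarray):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray, cache):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray):
        return self.forward(x)


def params_hash(module: Module) -> str:
    """Order-stable SHA-256 over every parameter array (freeze-discipline checks)."""
    h = hashlib.sha256()
    for name, arr in sorted(module.named_params()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


class Dense(Module):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params["W"] = fan_in_uniform(rng, (in_dim, out_dim), in_dim)
        self.params["b"] = fan_in_uniform(rng, (out_dim,), in_dim)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray):
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"Dense expected last dim {self.in_dim}, got {x.shape[-1]}")
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, dy: np.ndarray, cache):
        x = cache
        x2 = x.reshape(-1, self.in_dim)
        dy2 = dy.reshape(-1, self.out_dim)
        self.grads["W"] += x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return dy @ self.params["W"].T


class Conv1d(Module):
    """1-D convolution (cross-correlation), stride 1, 'same' length.

    Input ``[B, C_in, L]`` -> output ``[B, C_out, L]``.  Even kernels pad one
    sample more on the right, matching the usual 'same' convention.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel < 1:
            raise ValueError("kernel length must be >= 1")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        fan_in = in_channels * kernel
        self.params["W"] = fan_in_uniform(rng, (out_channels, in_channels, kernel), fan_in)
        self.params["b"] = fan_in_uniform(rng, (out_channels,), fan_in)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _pad(self, x: np.ndarray) -> np.ndarray:
        pl, pr = (self.k - 1) // 2, self.k // 2
        return np.pad(x, ((0, 0), (0, 0), (pl, pr)))

    def _windows(self, xp: np.ndarray, L: int) -> np.ndarray:
        B, C, _ = xp.shape
        s = xp.strides
        return as_strided(xp, shape=(B, C, L, self.k), strides=(s[0], s[1], s[2], s[2]))

    def forward(self, x: np.ndarray):
        if x.ndim != 3 or x.shape[1] != self.cin:
            raise ValueError(f"Conv1d expected [B, {self.cin}, L], got {x.shape}")
        if x.shape[2] < 1:
            raise ValueError("Conv1d input length must be >= 1")
        B, _, L = x.shape
        xp = self._pad(x)
        win = self._windows(xp, L)
        # [B, C, L, K] x [Cout, C, K] -> [B, L, Cout]
        y = np.tensordot(win, self.params["W"], axes=([1, 3], [1, 2]))
        y = y.transpose(0, 2, 1) + self.params["b"][None, :, None]
        return y, x

    def backward(self, dy: np.ndarray, cache):
        x = cache
        B, _, L = x.shape
        xp = self._pad(x)
        win = self._windows(xp, L)
        self.grads["W"] += np.tensordot(dy, win, axes=([0, 2], [0, 2]))
        self.grads["b"] += dy.sum(axis=(0, 2))
        # scatter dy back through each kernel tap
        dxp = np.zeros_like(xp)
        t = np.tensordot(dy, self.params["W"], axes=(1, 0))  # [B, L, C, K]
        for k in range(self.k):
            dxp[:, :, k : k + L] += t[:, :, :, k].transpose(0, 2, 1)
        pl = (self.k - 1) // 2
        return dxp[:, :, pl : pl + L]


class ReLU(Module):
    def forward(self, x: np.ndarray):
        return np.maximum(x, 0.0), x > 0

    def backward(self, dy: np.ndarray, cache):
        return dy * cache


class Sigmoid(Module):
    def forward(self, x: np.ndarray):
        y = sigmoid(x)
        return y, y

    def backward(self, dy: np.ndarray, cache):
        y = cache
        return dy * y * (1.0 - y)


class Tanh(Module):
    def forward(self, x: np.ndarray):
        y = np.tanh(x)
        return y, y

    def backward(self, dy: np.ndarray, cache):
        y = cache
        return dy * (1.0 - y * y)


class GlobalMaxPool1d(Module):
    """[B, C, L] -> [B, C], max over the length axis."""

    def forward(self, x: np.ndarray):
        idx = x.argmax(axis=2)
        y = np.take_along_axis(x, idx[:, :, None], axis=2)[:, :, 0]
        return y, (idx, x.shape)

    def backward(self, dy: np.ndarray, cache):
        idx, shape = cache
        dx = np.zeros(shape)
        np.put_along_axis(dx, idx[:, :, None], dy[:, :, None], axis=2)
        return dx


class TemporalMaxPool(Module):
    """[B, T, H] -> [B, T//factor, H], max over non-overlapping windows."""

    def __init__(self, factor: int = 2) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray):
        B, T, H = x.shape
        if T % self.factor:
            raise ValueError(f"sequence length {T} not divisible by pool factor {self.factor}")
        xr = x.reshape(B, T // self.factor, self.factor, H)
        idx = xr.argmax(axis=2)
        y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
        return y, (idx, x.shape)

    def backward(self, dy: np.ndarray, cache):
        idx, shape = cache
        B, T, H = shape
        dxr = np.zeros((B, T // self.factor, self.factor, H))
        np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        return dxr.reshape(shape)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.layers = list(modules)
        for i, m in enumerate(self.layers):
            self.add_child(str(i), m)

    def forward(self, x: np.ndarray):
        caches = []
        for m in self.layers:
            x, c = m.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, dy: np.ndarray, caches):
        for m, c in zip(reversed(self.layers), reversed(caches)):
            dy = m.backward(dy, c)
        return dy


class MLP(Sequential):
    """Fully connected stack; ReLU between layers, linear output.

    ``dims = [in, h1, ..., out]``; output non-linearities (softmax, sigmoid,
    tanh) are applied by the caller so the same trunk serves every head.
    """

    def __init__(self, dims: list[int], rng: np.random.Generator) -> None:
        if len(dims) < 2:
            raise ValueError("MLP needs at least an input and an output dim")
        layers: list[Module] = []
        for i in range(len(dims) - 1):
            layers.append(Dense(dims[i], dims[i + 1], rng))
            if i < len(dims) - 2:
                layers.append(ReLU())
        super().__init__(*layers)
        self.dims = list(dims)


class Adam:
    """Adam over the parameters of the given modules, in-place updates."""

    def __init__(self, modules: list[Module], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.modules = list(modules)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}
        for i, mod in enumerate(self.modules):
            self._m[i] = {k: np.zeros_like(v) for k, v in mod.named_params()}
            self._v[i] = {k: np.zeros_like(v) for k, v in mod.named_params()}

    def zero_grad(self) -> None:
        for mod in self.modules:
            mod.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, mod in enumerate(self.modules):
            grads = dict(mod.named_grads())
            for key, p in mod.named_params():
                g = grads[key]
                if self.weight_decay:
                    g = g + self.weight_decay * p
                m = self._m[i][key]
                v = self._v[i][key]
                m *= self.beta1
                m += (1.0 - self.beta1) * g
                v *= self.beta2
                v += (1.0 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def finite_difference_grad(f: Callable[[], float], arr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar ``f()`` w.r.t. ``arr`` (mutated in place)."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2.0 * eps)
    return g
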