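"""Minimal numpy neural-network toolkit (channels-last, float32).

Provides exactly the layers the force-regression architectures need —
2D/3D convolution, batch normalisation, ReLU, average pooling, global
average pooling and fully connected layers — together with an Adam
optimiser and a one-cycle learning-rate schedule.

Tensors are channels-last, ``(batch, *spatial, channels)``: convolution
then reduces to one GEMM over regular slices per kernel offset, with no
strided gather copies.

Layers are functional: ``forward`` returns ``(output, cache)`` and
``backward(cache, grad_out)`` returns the input gradient while
*accumulating* parameter gradients, so a module applied twice per step
(shared-weight Siamese branches) sums the gradients of both applications.
All gradients are exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Param", "Module", "Conv", "BatchNorm", "ReLU", "AvgPool",
    "GlobalAvgPool", "Linear", "Sequential", "Adam", "one_cycle_lr",
    "he_normal",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Module:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Conv(Module):
    """N-dimensional convolution (ndim 2 or 3), odd kernel, 'same' padding.

    The weight is stored as ``(kernel_offsets * c_in, c_out)`` with
    offset-major row order, matching the column layout assembled from one
    strided slice per offset.
    """

    def __init__(self, ndim: int, c_in: int, c_out: int, kernel: int = 3,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        rng = rng or np.random.default_rng(0)
        self.ndim = ndim
        self.c_in = c_in
        self.c_out = c_out
        self.kernel = kernel
        self.stride = stride
        self.pad = kernel // 2
        self.offsets = list(itertools.product(range(kernel), repeat=ndim))
        fan_in = c_in * kernel**ndim
        self.w = Param(he_normal(rng, (fan_in, c_out), fan_in), f"{name}.w")
        self.b = Param(np.zeros(c_out, dtype=np.float32), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.pad == 0:
            return x
        width = [(0, 0)] + [(self.pad, self.pad)] * self.ndim + [(0, 0)]
        return np.pad(x, width)

    def _slices(self, offset: tuple[int, ...], out_sp: tuple[int, ...]):
        s = self.stride
        return (slice(None),) + tuple(
            slice(o, o + s * n, s) for o, n in zip(offset, out_sp)
        ) + (slice(None),)

    def forward(self, x: np.ndarray, train: bool = True):
        if x.ndim != 2 + self.ndim or x.shape[-1] != self.c_in:
            raise ValueError(
                f"expected (B, spatial^{self.ndim}, {self.c_in}), got {x.shape}")
        if self.stride == 1 and self.kernel > 1 and self.c_out < self.c_in:
            return self._forward_shift(x)
        b = x.shape[0]
        xp = self._pad(np.asarray(x, dtype=np.float32))
        out_sp = tuple(
            (d + 2 * self.pad - self.kernel) // self.stride + 1
            for d in x.shape[1:-1]
        )
        n_off = len(self.offsets)
        cols = np.empty((b, *out_sp, n_off, self.c_in), dtype=np.float32)
        for m, off in enumerate(self.offsets):
            cols[..., m, :] = xp[self._slices(off, out_sp)]
        cols = cols.reshape(b, -1, n_off * self.c_in)
        y = cols @ self.w.value + self.b.value
        return y.reshape(b, *out_sp, self.c_out), ("im2col", cols, x.shape, out_sp)

    # -- shift-and-GEMM path (stride 1): one dense GEMM over all padded
    # positions, then one shifted slice-add per kernel offset.  Cheaper than
    # im2col whenever c_out < c_in (dense-block layers), because the k^d
    # expansion then happens on the narrow output side.
    def _dx_transposed(self, dy: np.ndarray, x_shape: tuple[int, ...]) -> np.ndarray:
        """Input gradient as a correlation of dy with the flipped kernel.

        For stride-1 'same' convolutions with few output channels this is
        much cheaper than scattering the k^d * c_in column gradient.
        """
        b = x_shape[0]
        sp = x_shape[1:-1]
        n_off = len(self.offsets)
        dyp = self._pad(np.ascontiguousarray(dy))
        cols = np.empty((b, *sp, n_off, self.c_out), dtype=np.float32)
        for m, off in enumerate(self.offsets):
            cols[..., m, :] = dyp[self._slices(off, sp)]
        # reversing the flattened offset list flips every kernel dimension
        w_back = np.ascontiguousarray(
            self.w.value.reshape(n_off, self.c_in, self.c_out)[::-1]
            .transpose(0, 2, 1).reshape(n_off * self.c_out, self.c_in))
        dx = cols.reshape(b, -1, n_off * self.c_out) @ w_back
        return dx.reshape(x_shape)

    def _w2(self) -> np.ndarray:
        n_off = len(self.offsets)
        return np.ascontiguousarray(
            self.w.value.reshape(n_off, self.c_in, self.c_out)
            .transpose(1, 0, 2).reshape(self.c_in, n_off * self.c_out))

    def _forward_shift(self, x: np.ndarray):
        b = x.shape[0]
        sp = x.shape[1:-1]
        xp = self._pad(np.asarray(x, dtype=np.float32))
        spp = xp.shape[1:-1]
        n_off = len(self.offsets)
        z = (xp.reshape(-1, self.c_in) @ self._w2()).reshape(
            b, *spp, n_off, self.c_out)
        y = np.full((b, *sp, self.c_out), self.b.value, dtype=np.float32)
        for m, off in enumerate(self.offsets):
            sl = (slice(None),) + tuple(
                slice(o, o + n) for o, n in zip(off, sp)) + (m, slice(None))
            y += z[sl]
        return y, ("shift", xp, x.shape)

    def _backward_shift(self, cache, dy: np.ndarray) -> np.ndarray:
        _, xp, x_shape = cache
        b = x_shape[0]
        sp = x_shape[1:-1]
        spp = xp.shape[1:-1]
        n_off = len(self.offsets)
        dz = np.zeros((b, *spp, n_off, self.c_out), dtype=np.float32)
        for m, off in enumerate(self.offsets):
            sl = (slice(None),) + tuple(
                slice(o, o + n) for o, n in zip(off, sp)) + (m, slice(None))
            dz[sl] = dy
        dzf = dz.reshape(-1, n_off * self.c_out)
        dw2 = xp.reshape(-1, self.c_in).T @ dzf
        self.w.grad += np.ascontiguousarray(
            dw2.reshape(self.c_in, n_off, self.c_out)
            .transpose(1, 0, 2).reshape(-1, self.c_out))
        self.b.grad += dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxp = (dzf @ self._w2().T).reshape(b, *spp, self.c_in)
        p = self.pad
        sl = (slice(None),) + (slice(p, -p),) * self.ndim + (slice(None),)
        return dxp[sl]

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        if cache[0] == "shift":
            return self._backward_shift(cache, dy)
        _, cols, x_shape, out_sp = cache
        b = x_shape[0]
        ck = self.w.value.shape[0]
        dyf = dy.reshape(b, -1, self.c_out)
        self.w.grad += cols.reshape(-1, ck).T @ dyf.reshape(-1, self.c_out)
        self.b.grad += dyf.sum(axis=(0, 1))
        if self.stride == 1 and self.kernel > 1 and self.c_out < self.c_in:
            return self._dx_transposed(dy, x_shape)
        dcols = (dyf @ self.w.value.T).reshape(
            b, *out_sp, len(self.offsets), self.c_in)
        pad_sp = [d + 2 * self.pad for d in x_shape[1:-1]]
        dxp = np.zeros((b, *pad_sp, self.c_in), dtype=np.float32)
        for m, off in enumerate(self.offsets):
            dxp[self._slices(off, out_sp)] += dcols[..., m, :]
        if self.pad == 0:
            return dxp
        sl = (slice(None),) + (slice(self.pad, -self.pad),) * self.ndim + (slice(None),)
        return dxp[sl]


class BatchNorm(Module):
    """Batch normalisation over all axes but the trailing channel axis."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = True):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        y = self.gamma.value * xhat + self.beta.value
        return y.astype(np.float32), (xhat, inv_std, axes, train)

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, train = cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value * inv_std
        if not train:
            return (dy * g).astype(np.float32)
        dx = g * (dy - dy.mean(axis=axes, keepdims=True)
                  - xhat * (dy * xhat).mean(axis=axes, keepdims=True))
        return dx.astype(np.float32)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True):
        mask = x > 0
        return x * mask, mask

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        return dy * cache


class AvgPool(Module):
    """Non-overlapping average pooling with window = stride = ``k``."""

    def __init__(self, ndim: int, k: int = 2) -> None:
        self.ndim = ndim
        self.k = k

    def forward(self, x: np.ndarray, train: bool = True):
        k = self.k
        sp = x.shape[1:-1]
        if any(s % k for s in sp):
            raise ValueError(f"spatial shape {sp} not divisible by {k}")
        b, c = x.shape[0], x.shape[-1]
        if self.ndim == 3:
            d, h, w = sp
            y = x.reshape(b, d // k, k, h // k, k, w // k, k, c).mean(axis=(2, 4, 6))
        else:
            h, w = sp
            y = x.reshape(b, h // k, k, w // k, k, c).mean(axis=(2, 4))
        return y, x.shape

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        k = self.k
        g = dy / (k**self.ndim)
        for ax in range(1, 1 + self.ndim):
            g = np.repeat(g, k, axis=ax)
        return g.astype(np.float32)


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray, train: bool = True):
        axes = tuple(range(1, x.ndim - 1))
        return x.mean(axis=axes), x.shape

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        x_shape = cache
        sp = x_shape[1:-1]
        scale = 1.0 / int(np.prod(sp))
        expand = (slice(None),) + (None,) * len(sp) + (slice(None),)
        return (np.broadcast_to(dy[expand], x_shape) * scale).astype(np.float32)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, name: str = "fc") -> None:
        rng = rng or np.random.default_rng(0)
        self.w = Param(he_normal(rng, (n_in, n_out), n_in), f"{name}.w")
        self.b = Param(np.zeros(n_out, dtype=np.float32), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True):
        return x @ self.w.value + self.b.value, x

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        x = cache
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return (dy @ self.w.value.T).astype(np.float32)


class Sequential(Module):
    def __init__(self, layers: Sequence[Module]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self) -> list[np.ndarray]:
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x: np.ndarray, train: bool = True):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, train)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy: np.ndarray) -> np.ndarray:
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(c, dy)
        return dy


class Adam:
    """Adam with the standard defaults (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params: Iterable[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad**2 - v)
            p.value -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def one_cycle_lr(step: int, total_steps: int, lr_min: float, lr_max: float,
                 pct_up: float = 0.3) -> float:
    """Cosine-shaped one-cycle schedule ramping lr_min -> lr_max -> lr_min."""
    if total_steps <= 1:
        return lr_max
    up = max(1, int(round(pct_up * total_steps)))
    if step < up:
        frac = step / up
        return lr_min + (lr_max - lr_min) * 0.5 * (1.0 - np.cos(np.pi * frac))
    frac = (step - up) / max(1, total_steps - up)
    return lr_min + (lr_max - lr_min) * 0.5 * (1.0 + np.cos(np.pi * frac))
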