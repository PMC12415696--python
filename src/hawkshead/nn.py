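"""Minimal deterministic neural-network engine.

Exactly the operators the tile classifier needs — 2-D convolution (stride 1,
same padding), 2x2 max pooling, global average pooling, dropout, dense
layers with optional L1/L2 penalties, ReLU/sigmoid — with hand-derived
backward passes and an Adam optimiser.  Everything is float32 and NHWC.

Convolutions run as im2col + BLAS matrix products, chunked over the batch
dimension so the unrolled column buffers stay small; the input gradient is
accumulated by kernel-offset shifted adds, which avoids an explicit
scatter-based col2im.  Given a seed (weight init, shuffling, dropout) the
whole engine is deterministic on a fixed BLAS configuration.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base layer: stateless unless it owns :class:`Param` objects."""

    def params(self) -> list[Param]:
        return []

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - default no-op
        pass

    def forward(self, x: np.ndarray, training: bool = False, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def penalty(self) -> float:
        return 0.0

    @property
    def width(self) -> Optional[int]:
        """Output channel/unit count where meaningful (for introspection)."""
        return None


class Conv2D(Layer):
    """Same-padded stride-1 convolution, NHWC, He-normal init.

    Two equivalent execution paths: shallow inputs (small ``k*k*cin``) use a
    chunked im2col + single GEMM; deep inputs use one GEMM per kernel offset
    on the contiguous padded tensor with shifted-slice accumulation, which
    avoids the large strided im2col gather entirely.
    """

    _IM2COL_MAX_PATCH = 128  # switch point for k*k*cin

    def __init__(self, in_channels: int, filters: int, kernel_size: int = 3, chunk: int = 16):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.in_channels = in_channels
        self.filters = filters
        self.k = kernel_size
        self.chunk = chunk
        self.W = Param(np.zeros((kernel_size, kernel_size, in_channels, filters)))
        self.b = Param(np.zeros(filters))
        self._xp: Optional[np.ndarray] = None

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.k * self.k * self.in_channels
        self.W.value = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=self.W.value.shape).astype(np.float32)
        self.b.value = np.zeros(self.filters, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.W, self.b]

    @property
    def width(self) -> int:
        return self.filters

    @property
    def _use_im2col(self) -> bool:
        return self.k * self.k * self.in_channels <= self._IM2COL_MAX_PATCH

    def _cols(self, xp_chunk: np.ndarray, h: int, w: int) -> np.ndarray:
        cols = sliding_window_view(xp_chunk, (self.k, self.k), axis=(1, 2))  # (m,h,w,cin,k,k)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))  # (m,h,w,k,k,cin)
        return cols.reshape(-1, self.k * self.k * self.in_channels)

    def forward(self, x, training=False, rng=None):
        n, h, w, cin = x.shape
        if cin != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {cin}")
        p = self.k // 2
        xp = np.pad(x.astype(np.float32, copy=False), ((0, 0), (p, p), (p, p), (0, 0)))
        if self._use_im2col:
            wmat = self.W.value.reshape(-1, self.filters)
            out = np.empty((n, h, w, self.filters), dtype=np.float32)
            for i in range(0, n, self.chunk):
                m = min(self.chunk, n - i)
                cols = self._cols(xp[i : i + m], h, w)
                out[i : i + m] = (cols @ wmat + self.b.value).reshape(m, h, w, self.filters)
        else:
            hp, wp = h + 2 * p, w + 2 * p
            xflat = xp.reshape(-1, cin)
            out = np.zeros((n, h, w, self.filters), dtype=np.float32)
            buf = np.empty((n * hp * wp, self.filters), dtype=np.float32)
            for ki in range(self.k):
                for kj in range(self.k):
                    np.matmul(xflat, self.W.value[ki, kj], out=buf)
                    out += buf.reshape(n, hp, wp, self.filters)[:, ki : ki + h, kj : kj + w, :]
            out += self.b.value
        if training:
            self._xp = xp
            self._hw = (h, w)
        return out

    def backward(self, grad):
        assert self._xp is not None, "backward before forward(training=True)"
        h, w = self._hw
        n = grad.shape[0]
        p = self.k // 2
        grad = grad.astype(np.float32, copy=False)
        if self._use_im2col:
            wmat = self.W.value.reshape(-1, self.filters)
            d_wmat = np.zeros_like(wmat)
            db = np.zeros_like(self.b.value)
            dxp = np.zeros_like(self._xp)
            for i in range(0, n, self.chunk):
                m = min(self.chunk, n - i)
                g = grad[i : i + m].reshape(-1, self.filters)
                cols = self._cols(self._xp[i : i + m], h, w)
                d_wmat += cols.T @ g
                db += g.sum(axis=0)
                dcols = (g @ wmat.T).reshape(m, h, w, self.k, self.k, self.in_channels)
                for ki in range(self.k):
                    for kj in range(self.k):
                        dxp[i : i + m, ki : ki + h, kj : kj + w, :] += dcols[:, :, :, ki, kj, :]
            self.W.grad = d_wmat.reshape(self.W.value.shape)
        else:
            hp, wp = h + 2 * p, w + 2 * p
            xflat = self._xp.reshape(-1, self.in_channels)
            gflat = grad.reshape(-1, self.filters)
            dw = np.empty_like(self.W.value)
            gpad = np.zeros((n, hp, wp, self.filters), dtype=np.float32)
            for ki in range(self.k):
                for kj in range(self.k):
                    gpad.fill(0.0)
                    gpad[:, ki : ki + h, kj : kj + w, :] = grad
                    dw[ki, kj] = xflat.T @ gpad.reshape(-1, self.filters)
            db = gflat.sum(axis=0)
            dxp = np.zeros_like(self._xp)
            for ki in range(self.k):
                for kj in range(self.k):
                    t = (gflat @ self.W.value[ki, kj].T).reshape(n, h, w, self.in_channels)
                    dxp[:, ki : ki + h, kj : kj + w, :] += t
            self.W.grad = dw
        self.b.grad = db
        self._xp = None
        return dxp[:, p : p + h, p : p + w, :]


class MaxPool2D(Layer):
    """Non-overlapping 2x2 max pooling.

    On ties every maximal position receives the full upstream gradient.
    Ties between strictly positive float activations have measure zero; the
    common tie (a ReLU-zeroed window) is irrelevant because the preceding
    ReLU backward masks those positions anyway.
    """

    def __init__(self, pool: int = 2):
        self.pool = pool
        self._cache = None

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        p = self.pool
        if h % p or w % p:
            raise ValueError(f"spatial dims {(h, w)} not divisible by pool {p}")
        r = x.reshape(n, h // p, p, w // p, p, c)
        out = r.max(axis=(2, 4))
        if training:
            self._cache = (r, out, x.shape)
        return out

    def backward(self, grad):
        r, out, shape = self._cache
        self._cache = None
        n, h, w, c = shape
        g = (r == out[:, :, None, :, None, :]) * grad[:, :, None, :, None, :]
        return g.reshape(n, h, w, c).astype(np.float32, copy=False)


class GlobalAveragePooling(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), (n, h, w, c)).astype(np.float32)


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(np.float32) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, l1: float = 0.0, l2: float = 0.0):
        self.in_features = in_features
        self.out_features = out_features
        self.l1 = float(l1)
        self.l2 = float(l2)
        self.W = Param(np.zeros((in_features, out_features)))
        self.b = Param(np.zeros(out_features))
        self._x = None

    def init(self, rng: np.random.Generator) -> None:
        self.W.value = rng.normal(0.0, math.sqrt(2.0 / self.in_features), size=self.W.value.shape).astype(np.float32)
        self.b.value = np.zeros(self.out_features, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.W, self.b]

    @property
    def width(self) -> int:
        return self.out_features

    def penalty(self) -> float:
        pen = 0.0
        if self.l1:
            pen += self.l1 * float(np.abs(self.W.value).sum())
        if self.l2:
            pen += self.l2 * float((self.W.value**2).sum())
        return pen

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        grad = grad.astype(np.float32, copy=False)
        self.W.grad = self._x.T @ grad
        if self.l2:
            self.W.grad += 2.0 * self.l2 * self.W.value
        if self.l1:
            self.W.grad += self.l1 * np.sign(self.W.value)
        self.b.grad = grad.sum(axis=0)
        dx = grad @ self.W.value.T
        self._x = None
        return dx


class ReLU(Layer):
    def __init__(self, inplace: bool = True):
        self.inplace = inplace

    def forward(self, x, training=False, rng=None):
        # in-place is safe here: upstream layers hand over freshly
        # allocated activations
        out = np.maximum(x, 0.0, out=x) if (self.inplace and x.flags.writeable) else np.maximum(x, 0.0)
        if training:
            self._out = out
        return out

    def backward(self, grad):
        g = grad * (self._out > 0)
        self._out = None
        return g


class Sigmoid(Layer):
    """Output activation.  The training loop differentiates the combined
    sigmoid + binary cross-entropy at the logits, so no backward is needed."""

    def forward(self, x, training=False, rng=None):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    def backward(self, grad):  # pragma: no cover - bypassed by design
        raise RuntimeError("Sigmoid.backward is bypassed; use backward_from_logits")


class Sequential:
    """A plain layer stack with a seam for the fused sigmoid/BCE gradient."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def initialize(self, rng: np.random.Generator) -> "Sequential":
        for layer in self.layers:
            layer.init(rng)
        return self

    def forward(self, x, training: bool = False, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward_from_logits(self, delta: np.ndarray) -> np.ndarray:
        """Backpropagate ``dL/dlogits`` through everything below the sigmoid."""
        if not isinstance(self.layers[-1], Sigmoid):
            raise RuntimeError("expected a Sigmoid output layer")
        g = delta
        for layer in reversed(self.layers[:-1]):
            g = layer.backward(g)
        return g

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def penalty(self) -> float:
        return sum(layer.penalty() for layer in self.layers)

    def architecture(self) -> list[tuple[str, Optional[int]]]:
        """(layer class name, width) pairs, for conformance checks."""
        return [(type(layer).__name__, layer.width) for layer in self.layers]

    # -- weight (de)serialisation -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} tensors, model has {len(params)}")
        for i, p in enumerate(params):
            value = np.asarray(state[f"param_{i}"], dtype=np.float32)
            if value.shape != p.value.shape:
                raise ValueError(f"shape mismatch for param_{i}: {value.shape} vs {p.value.shape}")
            p.value = value

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


class Adam:
    """Adam with an optional learning-rate schedule ``lr(step) -> float``."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float | Callable[[int], float] = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = list(params)
        self._lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def lr_at(self, step: int) -> float:
        return self._lr(step) if callable(self._lr) else self._lr

    def step(self) -> None:
        self.t += 1
        lr = self.lr_at(self.t)
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(p.grad)
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def exponential_decay(initial_lr: float, decay_rate: float = 0.96, decay_steps: int = 1000) -> Callable[[int], float]:
    """Smooth exponential schedule: ``lr = lr0 * rate**(step / steps)``."""

    def schedule(step: int) -> float:
        return initial_lr * decay_rate ** (step / decay_steps)

    return schedule


def binary_cross_entropy(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(probs.reshape(-1), eps, 1.0 - eps)
    y = labels.reshape(-1)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
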