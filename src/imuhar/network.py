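"""Minimal NumPy neural-network layers with reverse-mode gradients.

Implements exactly what the 1D-CNN classifier needs: valid (unpadded)
strided 1-D convolution, dense layers, ReLU, inverted dropout, softmax
cross-entropy and the AdamW optimizer with decoupled weight decay.
Convolution is computed as an im2col gather (stride-tricks view) followed
by one matrix multiply, so training stays practical on a single CPU.

Inputs are ``(batch, time, channels)`` float32 arrays throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class Param:
    """A learnable tensor with its gradient and AdamW state."""

    value: np.ndarray
    grad: np.ndarray = None  # type: ignore[assignment]
    m: np.ndarray = None  # type: ignore[assignment]
    v: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid strided 1-D convolution over (batch, time, channels)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        scale = math.sqrt(2.0 / (kernel * in_channels))  # He init for ReLU
        self.w = Param(rng.normal(0.0, scale,
                                  size=(kernel * in_channels, out_channels)
                                  ).astype(np.float32))
        self.b = Param(np.zeros(out_channels, dtype=np.float32))
        self._cols: np.ndarray | None = None
        self._in_length = 0

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, length, c = x.shape
        if length < self.kernel:
            raise ValueError(f"input length {length} < kernel {self.kernel}")
        # (n, L-K+1, C, K) view -> strided windows -> (n, L', K*C)
        view = sliding_window_view(x, self.kernel, axis=1)[:, :: self.stride]
        cols = np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(
            n, view.shape[1], self.kernel * c
        )
        self._cols = cols if train else None
        self._in_length = length
        return cols @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols
        n, l_out, _ = dout.shape
        kc = self.kernel * self.in_channels
        self.w.grad += cols.reshape(-1, kc).T @ dout.reshape(-1, self.out_channels)
        self.b.grad += dout.sum(axis=(0, 1))
        dcols = (dout @ self.w.value.T).reshape(
            n, l_out, self.kernel, self.in_channels
        )
        dx = np.zeros((n, self._in_length, self.in_channels), dtype=dout.dtype)
        offsets = np.arange(l_out) * self.stride
        for k in range(self.kernel):  # offsets+k are distinct for fixed k
            dx[:, offsets + k, :] += dcols[:, :, k, :]
        return dx


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator) -> None:
        scale = math.sqrt(2.0 / in_features)
        self.w = Param(rng.normal(0.0, scale, size=(in_features, out_features)
                                  ).astype(np.float32))
        self.b = Param(np.zeros(out_features, dtype=np.float32))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, p: float) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training without an rng")
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (
            1.0 - self.p
        )
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Sequential:
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, final_relu: bool = True
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``final_relu=True`` applies ReLU to the logits before the softmax (the
    output layer is ReLU-activated like every other layer); the gradient is
    masked accordingly.
    """
    z = np.maximum(logits, 0.0) if final_relu else logits
    p = softmax(z)
    n = logits.shape[0]
    eps = np.finfo(p.dtype).tiny
    loss = float(-np.log(p[np.arange(n), targets] + eps).mean())
    dz = p.copy()
    dz[np.arange(n), targets] -= 1.0
    dz /= n
    if final_relu:
        dz = dz * (logits > 0)
    return loss, dz.astype(logits.dtype)


class AdamW:
    """AdamW with decoupled weight decay, applied to every parameter."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p in self.params:
            p.value *= 1.0 - self.lr * self.weight_decay
            p.m = b1 * p.m + (1.0 - b1) * p.grad
            p.v = b2 * p.v + (1.0 - b2) * p.grad * p.grad
            m_hat = p.m / (1.0 - b1**self.t)
            v_hat = p.v / (1.0 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
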