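"""A compact, fully seeded neural-network engine for small 3D images.

Implements exactly the operations the pipeline needs — 3D convolution with
3x3x3 kernels, stride 1 and same padding; ReLU; flatten; dense layers; a
sigmoid/binary-cross-entropy head and a mean-squared-error head — with
manual backpropagation and an Adam optimizer, all in float32 numpy.
Convolutions are evaluated as im2col + matmul so batched CPU training of the
desk-scale models stays in BLAS.  Gradients are verified against central
finite differences in the test suite.

Everything is deterministic given the initialization seed and the data order.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Conv3D",
    "ReLU",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "mse_loss",
]

_K = 3  # kernel edge length; stride 1, same padding throughout


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, H, W, D, C) -> (N*H*W*D, 27*C) tap matrix with zero same-padding."""
    n, h, w, d, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n * h * w * d, _K**3 * c), dtype=np.float32)
    col = 0
    for i in range(_K):
        for j in range(_K):
            for k in range(_K):
                block = xp[:, i : i + h, j : j + w, k : k + d, :]
                cols[:, col : col + c] = block.reshape(-1, c)
                col += c
    return cols


class Conv3D:
    """3x3x3 convolution, stride 1, same (zero) padding.

    Kernel tensor shape (3, 3, 3, in_channels, out_channels); He-normal
    initialization from the supplied generator.  Narrow inputs (<= 2
    channels) evaluate as one im2col GEMM; wider inputs as 27 per-tap GEMMs,
    which avoids the large strided gather.  The input gradient also runs
    per-tap, and the leading layer of a network skips it entirely.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator) -> None:
        fan_in = _K**3 * in_channels
        scale = np.sqrt(2.0 / fan_in)
        self.kernel = (rng.standard_normal((_K, _K, _K, in_channels, out_channels)) * scale).astype(np.float32)
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self.needs_input_grad = True  # first layer of a net sets this False
        self._cols: Optional[np.ndarray] = None
        self._xp: Optional[np.ndarray] = None
        self._in_shape: Optional[Tuple[int, ...]] = None

    @property
    def in_channels(self) -> int:
        return self.kernel.shape[3]

    @property
    def out_channels(self) -> int:
        return self.kernel.shape[4]

    def _kernel_matrix(self) -> np.ndarray:
        # tap-major layout matching _im2col column order
        return self.kernel.reshape(-1, self.out_channels)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, d, cin = x.shape
        if cin <= 2:
            # narrow input: one wide GEMM on the tap matrix wins
            cols = _im2col(x)
            out = cols @ self._kernel_matrix() + self.bias
            if train:
                self._cols, self._xp, self._in_shape = cols, None, x.shape
        else:
            # wide input: 27 per-tap GEMMs avoid the large strided gather
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
            out = np.tile(self.bias, (n * h * w * d, 1))
            for i in range(_K):
                for j in range(_K):
                    for k in range(_K):
                        blk = np.ascontiguousarray(xp[:, i : i + h, j : j + w, k : k + d, :]).reshape(-1, cin)
                        out += blk @ self.kernel[i, j, k]
            if train:
                self._cols, self._xp, self._in_shape = None, xp, x.shape
        return out.reshape(n, h, w, d, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._in_shape is not None
        n, h, w, d, cin = self._in_shape
        dflat = dout.reshape(-1, self.out_channels)
        self.d_bias = dflat.sum(axis=0)
        if self._cols is not None:
            self.d_kernel = (self._cols.T @ dflat).reshape(self.kernel.shape)
        else:
            assert self._xp is not None
            self.d_kernel = np.empty_like(self.kernel)
            for i in range(_K):
                for j in range(_K):
                    for k in range(_K):
                        blk = np.ascontiguousarray(self._xp[:, i : i + h, j : j + w, k : k + d, :]).reshape(-1, cin)
                        self.d_kernel[i, j, k] = blk.T @ dflat
        self._cols = None
        self._xp = None
        if not self.needs_input_grad:
            return np.empty(0, dtype=np.float32)
        # dx: correlate dout with the spatially flipped, channel-transposed
        # kernel, as 27 per-tap GEMMs (no wide gather buffer)
        dop = np.pad(dout, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
        dx = np.zeros((n * h * w * d, cin), dtype=np.float32)
        for i in range(_K):
            for j in range(_K):
                for k in range(_K):
                    block = dop[:, i : i + h, j : j + w, k : k + d, :].reshape(-1, self.out_channels)
                    dx += block @ self.kernel[_K - 1 - i, _K - 1 - j, _K - 1 - k].T
        return dx.reshape(n, h, w, d, cin)

    def params(self) -> List[np.ndarray]:
        return [self.kernel, self.bias]

    def grads(self) -> List[np.ndarray]:
        return [self.d_kernel, self.d_bias]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []


class Flatten:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []


class Dense:
    """Fully connected layer, He-normal weights, zero bias."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / in_features)
        self.weight = (rng.standard_normal((in_features, out_features)) * scale).astype(np.float32)
        self.bias = np.zeros(out_features, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.d_weight = self._x.T @ dout
        self.d_bias = dout.sum(axis=0)
        return dout @ self.weight.T

    def params(self) -> List[np.ndarray]:
        return [self.weight, self.bias]

    def grads(self) -> List[np.ndarray]:
        return [self.d_weight, self.d_bias]


class Sequential:
    def __init__(self, layers: Sequence) -> None:
        self.layers = list(layers)
        # the input image needs no gradient, so the leading conv can skip dx
        if self.layers and isinstance(self.layers[0], Conv3D):
            self.layers[0].needs_input_grad = False

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                state[f"layer_{i}/param_{j}"] = p.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params()):
                p[...] = state[f"layer_{i}/param_{j}"]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class Adam:
    """Adam with the standard bias correction; state per parameter tensor."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(
    z: np.ndarray, y: np.ndarray, sample_weight: Optional[np.ndarray] = None
) -> Tuple[float, np.ndarray]:
    """(Weighted) mean binary cross-entropy on logits; returns (loss, dL/dz).

    ``sample_weight`` rescales each sample's contribution (it is normalized
    to mean one, so the loss scale is comparable across weightings).
    """
    z = z.astype(np.float64).ravel()
    y = y.astype(np.float64).ravel()
    per_sample = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    if sample_weight is None:
        w = np.ones_like(z)
    else:
        w = np.asarray(sample_weight, dtype=np.float64).ravel()
        w = w / w.mean()
    loss = float(np.mean(w * per_sample))
    dz = (w * (sigmoid(z) - y) / z.size).astype(np.float32).reshape(-1, 1)
    return loss, dz


def mse_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared error per element; returns (loss, dL/dpred)."""
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff**2))
    dpred = (2.0 * diff / diff.size).astype(np.float32)
    return loss, dpred
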