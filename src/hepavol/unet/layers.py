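"""Differentiable 3D layers on NumPy arrays.

Tensors are channels-first ``(C, D, H, W)`` float32. Each layer caches what
its backward pass needs; convolutions are evaluated as 27 BLAS matmuls over
shifted views of the zero-padded input, which keeps both passes dominated
by sgemm. All parameterised layers expose ``params()`` as a list of
``(name, value_array, grad_array)`` triples for the optimiser.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv3d(Layer):
    """k x k x k convolution, stride 1, 'same' zero padding (k odd)."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in) + (kernel,) * 3).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """im2col + one GEMM: the column matrix is cached for backward."""
        k, p = self.k, self.k // 2
        self._shape = x.shape[1:]
        D, H, W = self._shape
        n = D * H * W
        if k == 1:
            self._col = np.ascontiguousarray(x, dtype=np.float32).reshape(self.c_in, n)
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
            col = np.empty((self.c_in, k**3, D, H, W), dtype=np.float32)
            o = 0
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        col[:, o] = xp[:, i : i + D, j : j + H, l : l + W]
                        o += 1
            self._col = col.reshape(self.c_in * k**3, n)
        out = self.W.reshape(self.c_out, -1) @ self._col
        out += self.b[:, None]
        return out.reshape(self.c_out, D, H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        D, H, W = self._shape
        n = D * H * W
        doutf = np.ascontiguousarray(dout, dtype=np.float32).reshape(self.c_out, n)
        self.dW[...] = (doutf @ self._col.T).reshape(self.W.shape)
        self.db[:] = doutf.sum(axis=1)
        self._col = None
        if k == 1:
            return (self.W.reshape(self.c_out, -1).T @ doutf).reshape(self.c_in, D, H, W)
        # dx is the 'same'-padded convolution of dout with the channel-
        # transposed, spatially flipped kernel; one GEMM with a large
        # inner dimension (c_out * k^3) instead of a rank-c_out update
        dp = np.pad(doutf.reshape(self.c_out, D, H, W), ((0, 0), (p, p), (p, p), (p, p)))
        dcol = np.empty((self.c_out, k**3, D, H, W), dtype=np.float32)
        o = 0
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dcol[:, o] = dp[:, i : i + D, j : j + H, l : l + W]
                    o += 1
        w_flip = self.W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        w_flip = np.ascontiguousarray(w_flip).reshape(self.c_in, -1)
        dx = w_flip @ dcol.reshape(self.c_out * k**3, n)
        return dx.reshape(self.c_in, D, H, W)


class GroupNorm(Layer):
    """Group normalisation over (channel-group, spatial), with affine."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        self.groups = max(1, min(groups, channels))
        while channels % self.groups:
            self.groups -= 1  # clamp to a divisor of the channel count
        self.channels = channels
        self.eps = eps
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        g = self.groups
        xg = x.reshape(g, -1)
        mean = xg.mean(axis=1, keepdims=True)
        var = xg.var(axis=1, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = ((xg - mean) * self._istd).astype(np.float32)
        out = self._xhat.reshape(self._shape) * self.gamma[:, None, None, None]
        out += self.beta[:, None, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat_full = self._xhat.reshape(self._shape)
        self.dgamma[:] = (dout * xhat_full).sum(axis=(1, 2, 3))
        self.dbeta[:] = dout.sum(axis=(1, 2, 3))
        g = self.groups
        dxhat = (dout * self.gamma[:, None, None, None]).reshape(g, -1)
        xhat = self._xhat
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
        dx = self._istd * (dxhat - m1 - xhat * m2)
        self._xhat = None
        return dx.reshape(self._shape).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dout, 0.0).astype(np.float32)
        self._mask = None
        return out


class MaxPool3d(Layer):
    """2 x 2 x 2 max pooling; even spatial extents required."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"max-pool requires even spatial extents, got {(d, h, w)}")
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        self._arg = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(blocks, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d, h, w = self._in_shape
        blocks = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(blocks, self._arg[..., None], dout[..., None], axis=-1)
        blocks = blocks.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        blocks = blocks.transpose(0, 1, 4, 2, 5, 3, 6)
        self._arg = None
        return blocks.reshape(c, d, h, w)


class UpsampleNearest(Layer):
    """Nearest-neighbour 2x upsampling along each spatial axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d, h, w = dout.shape
        return (
            dout.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .sum(axis=(2, 4, 6))
            .astype(np.float32)
        )


class ConvBlock(Layer):
    """Two (conv -> group norm -> ReLU) stages, the U-Net building block."""

    def __init__(self, c_in: int, c_out: int, gn_groups: int, rng: np.random.Generator):
        self.layers = [
            Conv3d(c_in, c_out, 3, rng),
            GroupNorm(c_out, gn_groups),
            ReLU(),
            Conv3d(c_out, c_out, 3, rng),
            GroupNorm(c_out, gn_groups),
            ReLU(),
        ]

    def params(self):
        return [
            (f"l{i}.{name}", value, grad)
            for i, layer in enumerate(self.layers)
            for name, value, grad in layer.params()
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    """Adam optimiser over the (value, grad) pairs of a network."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (_, value, grad) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * grad**2
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
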