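"""A small, CPU-only 3D convolutional network engine.

Implements exactly what the age-regression model needs and nothing more:
3D convolutions (im2col via strided slice gathers, matmul through BLAS),
ReLU, average pooling, global average pooling, a fixed feature gain, a
linear scalar head, and SGD with momentum and inverse-time learning-rate
decay.  Everything is float32 and deterministic for a fixed seed and thread
count.

The backward pass is hand-derived; ``tests`` verify it against finite
differences on tiny networks.
"""

from __future__ import annotations

import itertools

import numpy as np


class Layer:
    """Base class: layers own parameters, gradients and a forward/backward pair."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    #: set by Sequential on the first layer: its input gradient is never used
    skip_input_grad: bool = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, odd kernel, 'same'-style zero padding of kernel//2."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        # He initialization for ReLU networks.
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.params = [w.astype(np.float32), np.zeros(c_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._offsets = list(itertools.product(range(kernel), repeat=3))

    def _out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        k, s, p = self.kernel, self.stride, self.kernel // 2
        return tuple((d + 2 * p - k) // s + 1 for d in spatial)

    def _im2col(self, xpad: np.ndarray, out_sp: tuple[int, int, int]) -> np.ndarray:
        n = xpad.shape[0]
        s = self.stride
        do, ho, wo = out_sp
        cols = np.empty((n, self.c_in, len(self._offsets), do, ho, wo), dtype=np.float32)
        for idx, (i, j, l) in enumerate(self._offsets):
            cols[:, :, idx] = xpad[:, :, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s]
        return cols.reshape(n, self.c_in * len(self._offsets), do * ho * wo)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.kernel // 2
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        out_sp = self._out_shape(x.shape[2:])
        cols = self._im2col(xpad, out_sp)
        w, b = self.params
        out = np.matmul(w, cols) + b[:, None]
        if train:
            self._cache = (cols, xpad.shape, x.shape, out_sp)
        return out.reshape(x.shape[0], self.c_out, *out_sp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, pad_shape, x_shape, out_sp = self._cache
        n = dout.shape[0]
        do, ho, wo = out_sp
        doutm = dout.reshape(n, self.c_out, do * ho * wo)
        w, _ = self.params
        self.grads[0] += np.einsum("ncp,nkp->ck", doutm, cols, optimize=True)
        self.grads[1] += doutm.sum(axis=(0, 2))
        if self.skip_input_grad:
            return dout  # first layer: input gradient is never consumed
        dcols = np.matmul(w.T, doutm).reshape(
            n, self.c_in, len(self._offsets), do, ho, wo
        )
        dxpad = np.zeros(pad_shape, dtype=np.float32)
        s = self.stride
        for idx, (i, j, l) in enumerate(self._offsets):
            dxpad[:, :, i:i + s * do:s, j:j + s * ho:s, l:l + s * wo:s] += dcols[:, :, idx]
        p = self.kernel // 2
        return dxpad[:, :, p:p + x_shape[2], p:p + x_shape[3], p:p + x_shape[4]]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool3d(Layer):
    """Non-overlapping average pooling by an integer factor per axis."""

    def __init__(self, factor: int) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.factor
        n, c, d, h, w = x.shape
        if d % f or h % f or w % f:
            raise ValueError("spatial dims must be divisible by the pool factor")
        self._in_shape = x.shape
        return x.reshape(n, c, d // f, f, h // f, f, w // f, f).mean(axis=(3, 5, 7))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f = self.factor
        scaled = dout / f**3
        out = np.repeat(np.repeat(np.repeat(scaled, f, axis=2), f, axis=3), f, axis=4)
        return np.ascontiguousarray(out.reshape(self._in_shape))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        vol = int(np.prod(self._spatial))
        return np.broadcast_to(
            (dout / vol)[:, :, None, None, None],
            dout.shape + self._spatial,
        ).astype(np.float32)


class Scale(Layer):
    """Fixed (non-trainable) multiplicative gain."""

    def __init__(self, gain: float) -> None:
        super().__init__()
        self.gain = float(gain)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x * self.gain

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.gain


class LinearHead(Layer):
    """Dense layer mapping a feature vector to one scalar (years)."""

    def __init__(self, c_in: int, rng: np.random.Generator | None = None,
                 init_std: float = 0.01) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = [
            rng.normal(0.0, init_std, size=c_in).astype(np.float32),
            np.zeros(1, dtype=np.float32),
        ]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        w, b = self.params
        return x @ w + b[0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0] += self._x.T @ dout
        self.grads[1] += dout.sum(keepdims=True)
        return np.outer(dout, w)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        if layers:
            layers[0].skip_input_grad = True

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for g in self.gradients:
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)


class SGD:
    """Stochastic gradient descent with momentum and inverse-time lr decay.

    The learning rate at optimizer step t (0-based) is lr / (1 + decay * t).
    """

    def __init__(self, net: Sequential, lr: float, momentum: float, decay: float) -> None:
        self.net = net
        self.lr, self.momentum, self.decay = lr, momentum, decay
        self.velocity = [np.zeros_like(p) for p in net.parameters]
        self.t = 0

    @property
    def current_lr(self) -> float:
        return self.lr / (1.0 + self.decay * self.t)

    def step(self) -> None:
        lr_t = self.current_lr
        for p, g, v in zip(self.net.parameters, self.net.gradients, self.velocity):
            v *= self.momentum
            v -= lr_t * g
            p += v
        self.t += 1


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient with respect to predictions."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff).astype(np.float32) / len(diff)
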