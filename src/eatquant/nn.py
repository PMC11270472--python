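"""Minimal numpy neural-network engine for the classifier and segmenter.

Layers implement explicit ``forward``/``backward`` passes with caches, and the
networks compose them by hand (no autograd).  Convolutions are lowered to GEMM
through im2col; the input-gradient pass is itself a convolution with the
spatially flipped, channel-transposed kernel, so no scatter-add is needed.
Tensors are ``(N, C, H, W)`` float32 throughout.

Only what the two models need is implemented: 3x3/1x1 same-padding stride-1
convolutions, batch normalization, ReLU, 2x2 max pooling, 2x nearest-neighbor
upsampling, channel concatenation, dropout, global average pooling and a dense
head — plus RMSProp and Adam optimizers with per-epoch learning-rate schedules
driven by the trainers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _f32(x):
    return np.ascontiguousarray(x, dtype=np.float32)


class Layer:
    """Base class: parameterized layers override params/grads/buffers."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trained state (e.g. batch-norm running stats)."""
        return []


class Conv2D(Layer):
    """Same-padding, stride-1 convolution (kernel 3 or 1), He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k, self.pad = k, (k - 1) // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = _f32(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))  # n,c,h,w,k,k
        return _f32(win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        col = self._im2col(x)
        wmat = self.W.reshape(self.W.shape[0], -1)
        y = col @ wmat.T + self.b
        self._cache = (col, x.shape)
        return y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, xshape = self._cache
        n, c, h, w = xshape
        dymat = _f32(dy.transpose(0, 2, 3, 1).reshape(n * h * w, -1))
        self.dW[...] = (dymat.T @ col).reshape(self.W.shape)
        self.db[...] = dymat.sum(axis=0)
        # dX = conv(dY, flip(W) with channels transposed)
        wrot = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        dyt = dy if self.pad == 0 and self.k == 1 else dy
        if self.pad:
            dyt = np.pad(dy, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        win = sliding_window_view(dyt, (self.k, self.k), axis=(2, 3))
        dycol = _f32(win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, -1))
        dx = dycol @ wrot.reshape(c, -1).T
        self._cache = None
        return _f32(dx.reshape(n, h, w, c).transpose(0, 3, 1, 2))


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        ax = (0, 2, 3)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape) if train else None
        return _f32(self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, xshape = self._cache
        n, c, h, w = xshape
        m = n * h * w
        ax = (0, 2, 3)
        self.dgamma[...] = (dy * xhat).sum(axis=ax)
        self.dbeta[...] = dy.sum(axis=ax)
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        dx = g * (dy - dy.mean(axis=ax, keepdims=True) - xhat * (dy * xhat).mean(axis=ax, keepdims=True))
        self._cache = None
        return _f32(dx)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; requires even spatial dims."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "MaxPool2 needs even spatial dims"
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._mask = xr == y[:, :, :, None, :, None]
        self._shape = x.shape
        return _f32(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dyr = dy[:, :, :, None, :, None] * self._mask
        return _f32(dyr.reshape(n, c, h, w))


class Upsample2(Layer):
    """2x nearest-neighbor upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return _f32(x.repeat(2, axis=2).repeat(2, axis=3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return _f32(dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)))


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return _f32(x * self._mask)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else _f32(dy * self._mask)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return _f32(x.mean(axis=(2, 3)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return _f32(np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w))


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = _f32(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return _f32(x @ self.W + self.b)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return _f32(dy @ self.W.T)


# ---------------------------------------------------------------------------
# composite blocks
# ---------------------------------------------------------------------------

class ConvBNReLU(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.conv = Conv2D(c_in, c_out, k, rng)
        self.bn = BatchNorm2D(c_out)
        self.relu = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def grads(self):
        return self.conv.grads() + self.bn.grads()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class ResBlock(Layer):
    """Two 3x3 conv-BN units with an identity (or 1x1-projected) skip."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2D(c_in, c_out, 3, rng)
        self.bn1 = BatchNorm2D(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm2D(c_out)
        self.relu_out = ReLU()
        if c_in != c_out:
            self.proj = Conv2D(c_in, c_out, 1, rng)
            self.proj_bn = BatchNorm2D(c_out)
        else:
            self.proj = None

    def _sub(self):
        subs = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            subs += [self.proj, self.proj_bn]
        return subs

    def params(self):
        return [p for s in self._sub() for p in s.params()]

    def grads(self):
        return [g for s in self._sub() for g in s.grads()]

    def forward(self, x, train=True):
        idn = x if self.proj is None else self.proj_bn.forward(self.proj.forward(x, train), train)
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        return self.relu_out.forward(h + idn, train)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        dh = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(dy))))
        )
        didn = dy if self.proj is None else self.proj.backward(self.proj_bn.backward(dy))
        return dh + didn


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class Optimizer:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float):
        self.params, self.grads, self.lr = params, grads, lr


class RMSProp(Optimizer):
    def __init__(self, params, grads, lr=1e-4, rho=0.9, eps=1e-7):
        super().__init__(params, grads, lr)
        self.rho, self.eps = rho, eps
        self.v = [np.zeros_like(p) for p in params]

    def step(self):
        for p, g, v in zip(self.params, self.grads, self.v):
            v *= self.rho
            v += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + self.eps)


class Adam(Optimizer):
    def __init__(self, params, grads, lr=1e-4, b1=0.9, b2=0.999, eps=1e-8):
        super().__init__(params, grads, lr)
        self.b1, self.b2, self.eps, self.t = b1, b2, eps, 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self):
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def flatten_params(layers: list[Layer]) -> tuple[list[np.ndarray], list[np.ndarray]]:
    params = [p for l in layers for p in l.params()]
    grads = [g for l in layers for g in l.grads()]
    return params, grads


def save_state(layers: list[Layer]) -> list[np.ndarray]:
    """Copy all parameters and buffers (BN running stats) for checkpointing."""
    return [a.copy() for l in layers for a in (*l.params(), *l.buffers())]


def load_state(layers: list[Layer], saved: list[np.ndarray]) -> None:
    arrays = [a for l in layers for a in (*l.params(), *l.buffers())]
    if len(arrays) != len(saved):
        raise ValueError("state array count mismatch")
    for a, s in zip(arrays, saved):
        a[...] = s


def composite_subs(block) -> list[Layer]:
    """Flatten composite blocks so buffers are reachable."""
    if isinstance(block, ResBlock):
        return block._sub()
    if isinstance(block, ConvBNReLU):
        return [block.conv, block.bn]
    return [block]


def all_leaf_layers(layers: list[Layer]) -> list[Layer]:
    return [leaf for l in layers for leaf in composite_subs(l)]
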