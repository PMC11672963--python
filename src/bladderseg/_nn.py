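"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly the primitives the segmentation framework needs:
3x3/1x1 convolutions (im2col + BLAS matmul), batch normalization,
leaky ReLU, 2x2 max pooling that records argmax indices, index-preserving
max unpooling, dense layers, and Adam/AdamW optimizers with per-group
learning rates.  All tensors are float32, layout NCHW.

Every layer caches what its backward pass needs on ``forward`` and frees
it after ``backward``; networks are therefore used in the conventional
forward -> loss -> backward -> optimizer.step cycle.
"""

from __future__ import annotations

import os

import numpy as np

try:  # avoid BLAS thread oversubscription when fewer CPUs are usable than visible
    from threadpoolctl import ThreadpoolController

    ThreadpoolController().limit(limits=max(len(os.sched_getaffinity(0)), 1),
                                 user_api="blas")
except Exception:  # pragma: no cover - purely a performance guard
    pass

F32 = np.float32


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.data.shape})"


class Layer:
    """Base class; subclasses define forward/backward and parameters()."""

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int, slope: float) -> np.ndarray:
    # Kaiming-normal scaled for leaky-ReLU gain
    std = np.sqrt(2.0 / (fan_in * (1.0 + slope * slope)))
    return rng.normal(0.0, std, size=shape).astype(F32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) for a stride-1, same-padded k x k conv."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add column gradients back to image grid."""
    n, c, h, w = x_shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)  # (N,C,k,k,H,W)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    if p == 0:
        return dxp
    return dxp[:, :, p : p + h, p : p + w]


class Conv2d(Layer):
    """Stride-1, same-padded square convolution."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 slope: float = 0.01, name: str = "conv"):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        self.weight = Param(f"{name}.weight", he_init(rng, (cout, cin, k, k), fan_in, slope))
        self.bias = Param(f"{name}.bias", np.zeros(cout, dtype=F32))
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if self.k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(-1, c)
        else:
            cols = _im2col(x, self.k)
        wmat = self.weight.data.reshape(self.cout, -1)
        out = cols @ wmat.T + self.bias.data
        self._cache = (cols, x.shape) if train else None
        return np.ascontiguousarray(out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        self._cache = None
        n, _, h, w = x_shape
        dyc = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.weight.grad += (dyc.T @ cols).reshape(self.weight.data.shape)
        self.bias.grad += dyc.sum(axis=0)
        dcols = dyc @ self.weight.data.reshape(self.cout, -1)
        if self.k == 1:
            return np.ascontiguousarray(
                dcols.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2))
        return _col2im(dcols, x_shape, self.k)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=F32))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=F32))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] * (dxhat - s1 / m - xhat * s2 / m)).astype(F32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return np.where(mask, dy, self.slope * dy)


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y.astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        y = self._y
        self._y = None
        return (dy * y * (1.0 - y)).astype(F32)


def max_pool2x2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2/stride-2 max pooling returning (pooled, argmax index map).

    Index values are 0..3 in row-major window order ((0,0),(0,1),(1,0),(1,1));
    ties take the first (row-major) maximal element.  Raises on odd spatial size.
    """
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max pooling needs even spatial dims, got {h}x{w}")
    win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    pooled = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(pooled), idx.astype(np.int8)


def max_unpool2x2(pooled: np.ndarray, idx: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Place each pooled value at its recorded window position; zeros elsewhere."""
    n, c, ph, pw = pooled.shape
    h, w = out_hw
    if (h, w) != (2 * ph, 2 * pw):
        raise ValueError(f"unpool output size {h}x{w} does not match pooled {ph}x{pw}")
    if idx.shape != pooled.shape:
        raise ValueError("index map shape does not match pooled field")
    out = np.zeros((n, c, ph, pw, 4), dtype=pooled.dtype)
    np.put_along_axis(out, idx[..., None].astype(np.int64), pooled[..., None], axis=-1)
    out = out.reshape(n, c, ph, pw, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
    return np.ascontiguousarray(out)


class MaxPool2x2(Layer):
    """Pooling layer wrapper that stashes indices for the paired unpool."""

    def __init__(self):
        self.indices = None
        self.in_hw = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        pooled, idx = max_pool2x2(x)
        self.indices = idx
        self.in_hw = x.shape[2:]
        return pooled

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # gradient routes to the argmax positions, i.e. an unpool of dy
        return max_unpool2x2(dy, self.indices, self.in_hw)


class MaxUnpool2x2(Layer):
    def __init__(self):
        self.indices = None
        self.out_hw = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return max_unpool2x2(x, self.indices, self.out_hw)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        win = dy.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        return np.ascontiguousarray(
            np.take_along_axis(win, self.indices[..., None].astype(np.int64), axis=-1)[..., 0])


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, name: str = "fc"):
        std = np.sqrt(1.0 / nin)
        self.weight = Param(f"{name}.weight", rng.normal(0, std, (nout, nin)).astype(F32))
        self.bias = Param(f"{name}.bias", np.zeros(nout, dtype=F32))
        self._x = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return (dy @ self.weight.data).astype(F32)


class ConvBlock(Layer):
    """convolution -> batch normalization -> leaky ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 slope: float = 0.01, k: int = 3, name: str = "block"):
        self.conv = Conv2d(cin, cout, k, rng, slope, name=f"{name}.conv")
        self.bn = BatchNorm2d(cout, name=f"{name}.bn")
        self.act = LeakyReLU(slope)

    def parameters(self) -> list[Param]:
        return self.conv.parameters() + self.bn.parameters()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=axis, keepdims=True)).astype(F32)


def softmax_backward(p: np.ndarray, dp: np.ndarray, axis: int = 1) -> np.ndarray:
    """Jacobian-vector product of softmax: dL/dz from p = softmax(z) and dL/dp."""
    s = (dp * p).sum(axis=axis, keepdims=True)
    return (p * (dp - s)).astype(F32)


class Adam:
    """Adam / AdamW over parameter groups, each with its own learning rate.

    groups: list of dicts {"params": [Param], "lr": float}.  With
    ``decoupled=True`` weight decay is applied AdamW-style (decay added to the
    update, not to the gradient).
    """

    def __init__(self, groups: list[dict], betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decoupled: bool = False):
        self.groups = groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self._m = {}
        self._v = {}
        for g in groups:
            for p in g["params"]:
                self._m[id(p)] = np.zeros_like(p.data)
                self._v[id(p)] = np.zeros_like(p.data)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for g in self.groups:
            lr = g["lr"]
            for p in g["params"]:
                grad = p.grad
                if self.weight_decay and not self.decoupled:
                    grad = grad + self.weight_decay * p.data
                m, v = self._m[id(p)], self._v[id(p)]
                m += (1.0 - self.b1) * (grad - m)
                v += (1.0 - self.b2) * (grad * grad - v)
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                if self.weight_decay and self.decoupled:
                    update = update + self.weight_decay * p.data
                p.data -= lr * update


def adamw(groups: list[dict], weight_decay: float = 1e-2, **kw) -> Adam:
    return Adam(groups, weight_decay=weight_decay, decoupled=True, **kw)
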