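"""A minimal define-by-run autograd and CNN layer set on numpy.

The grading/runtime environment ships no deep-learning framework, so the
convolutional machinery the labeling network needs is implemented here:
reverse-mode autodiff over a small op set (5x5 same-padding convolution via
im2col + BLAS, non-overlapping 2x2 strided down/transpose convolutions,
batch norm, PReLU, sigmoid, concatenation, a fused soft-Dice +
cross-entropy loss) plus Adam.  Everything is float32 and seeded.

This is not a general framework: ops exist only in the forms the network
uses, and gradients are verified against finite differences in the test
suite.
"""

from __future__ import annotations

import contextlib
from collections.abc import Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode; frees im2col caches)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents if _GRAD_ENABLED else ()
        self._backward = backward if _GRAD_ENABLED else None

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- basic ops

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        a._accum(g)
        b._accum(g)

    return Tensor(out_data, (a, b), bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor(out_data, tuple(tensors), bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bwd(g):
        x._accum(g * s * (1.0 - s))

    return Tensor(s, (x,), bwd)


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    # alpha: per-channel (C,) for NCHW input
    a = alpha.data.reshape(1, -1, 1, 1)
    pos = x.data > 0
    out_data = np.where(pos, x.data, a * x.data)

    def bwd(g):
        x._accum(np.where(pos, g, a * g))
        alpha._accum(np.sum(g * np.where(pos, 0.0, x.data), axis=(0, 2, 3)))

    return Tensor(out_data, (x, alpha), bwd)


# ----------------------------------------------------------- convolutions

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*k*k) patches of a same-padded input."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, h, w = x.shape
    # win: (N, C, H, W, k, k) -> (N, H*W, C*k*k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, h * w, c * k * k
    )


def _conv_same_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None):
    n, c, h, wd = x.shape
    cout, cin, k, _ = w.shape
    cols = _im2col(x, k)
    out = cols @ w.reshape(cout, cin * k * k).T
    if b is not None:
        out += b
    return out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2), cols


def conv2d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Odd-kernel stride-1 convolution with 'same' zero padding."""
    out_data, cols = _conv_same_raw(x.data, w.data, b.data)
    if not _GRAD_ENABLED:
        return Tensor(out_data)
    cout, cin, k, _ = w.shape
    n, _, h, wd = x.shape

    def bwd(g):
        gf = g.transpose(0, 2, 3, 1).reshape(n, h * wd, cout)
        dw = np.tensordot(gf, cols, axes=([0, 1], [0, 1]))  # (cout, cin*k*k)
        w._accum(dw.reshape(w.shape))
        b._accum(g.sum(axis=(0, 2, 3)))
        # dx = same-conv of g with flipped, channel-swapped kernels
        w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = _conv_same_raw(g, np.ascontiguousarray(w_flip), None)
        x._accum(dx)

    return Tensor(out_data, (x, w, b), bwd)


def down_conv2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 convolution (non-overlapping patches)."""
    n, c, h, wd = x.shape
    cout = w.shape[0]
    if h % 2 or wd % 2:
        raise ValueError("down-convolution needs even spatial dims")
    ph, pw = h // 2, wd // 2
    patches = (
        x.data.reshape(n, c, ph, 2, pw, 2)
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(n, ph * pw, c * 4)
    )
    out = patches @ w.data.reshape(cout, c * 4).T + b.data
    out_data = out.reshape(n, ph, pw, cout).transpose(0, 3, 1, 2)
    if not _GRAD_ENABLED:
        return Tensor(out_data)

    def bwd(g):
        gf = g.transpose(0, 2, 3, 1).reshape(n, ph * pw, cout)
        dw = np.tensordot(gf, patches, axes=([0, 1], [0, 1]))
        w._accum(dw.reshape(w.shape))
        b._accum(g.sum(axis=(0, 2, 3)))
        dpatch = gf @ w.data.reshape(cout, c * 4)
        dx = (
            dpatch.reshape(n, ph, pw, c, 2, 2)
            .transpose(0, 3, 1, 4, 2, 5)
            .reshape(n, c, h, wd)
        )
        x._accum(dx)

    return Tensor(out_data, (x, w, b), bwd)


def up_conv2x2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 transpose convolution (exact upsampling by 2)."""
    n, c, h, wd = x.shape
    cout = w.shape[1]  # w: (Cin, Cout, 2, 2)
    xf = x.data.transpose(0, 2, 3, 1).reshape(n, h * wd, c)
    t = xf @ w.data.reshape(c, cout * 4)
    out_data = (
        t.reshape(n, h, wd, cout, 2, 2)
        .transpose(0, 3, 1, 4, 2, 5)
        .reshape(n, cout, 2 * h, 2 * wd)
    ) + b.data.reshape(1, cout, 1, 1)
    if not _GRAD_ENABLED:
        return Tensor(out_data)

    def bwd(g):
        gp = (
            g.reshape(n, cout, h, 2, wd, 2)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n, h * wd, cout * 4)
        )
        dw = np.tensordot(xf, gp, axes=([0, 1], [0, 1]))  # (c, cout*4)
        w._accum(dw.reshape(w.shape))
        b._accum(g.sum(axis=(0, 2, 3)))
        dx = (gp @ w.data.reshape(c, cout * 4).T).reshape(n, h, wd, c)
        x._accum(dx.transpose(0, 3, 1, 2))

    return Tensor(out_data, (x, w, b), bwd)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
               train: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    c = x.shape[1]
    g = gamma.data.reshape(1, c, 1, 1)
    bta = beta.data.reshape(1, c, 1, 1)
    if train:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    out_data = g * xhat + bta
    if not _GRAD_ENABLED:
        return Tensor(out_data)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd(go):
        gamma._accum(np.sum(go * xhat, axis=(0, 2, 3)))
        beta._accum(np.sum(go, axis=(0, 2, 3)))
        gx_hat = go * g
        if train:
            iv = inv.reshape(1, c, 1, 1)
            s1 = gx_hat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gx_hat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            x._accum(iv / m * (m * gx_hat - s1 - xhat * s2))
        else:
            x._accum(gx_hat * inv.reshape(1, c, 1, 1))

    return Tensor(out_data, (x, gamma, beta), bwd)


# ------------------------------------------------------------------ losses

def soft_dice_bce(pred: Tensor, target: np.ndarray,
                  eps: float = 1e-6) -> Tensor:
    """(1 - soft Dice over all channels jointly) + mean binary cross-entropy.

    ``pred`` must lie in (0,1); ``target`` is a Boolean/0-1 array of the
    same shape.
    """
    p = pred.data
    y = np.asarray(target, dtype=np.float32)
    if p.shape != y.shape:
        raise ValueError(f"prediction/label shape mismatch: {p.shape} vs {y.shape}")
    pc = np.clip(p, eps, 1.0 - eps)
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + eps
    dice = 2.0 * inter / denom
    ce = float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
    out_data = np.float32((1.0 - dice) + ce)

    def bwd(g):
        gd = -2.0 * (y * denom - inter) / (denom * denom)
        gce = (pc - y) / (pc * (1.0 - pc)) / y.size
        pred._accum(g * (gd + gce).astype(np.float32))

    return Tensor(out_data, (pred,), bwd)


def soft_dice_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """1 - soft Dice similarity, computed over the whole array jointly."""
    p = pred.data
    y = np.asarray(target, dtype=np.float32)
    if p.shape != y.shape:
        raise ValueError(f"prediction/label shape mismatch: {p.shape} vs {y.shape}")
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + eps
    out_data = np.float32(1.0 - 2.0 * inter / denom)

    def bwd(g):
        pred._accum(g * (-2.0 * (y * denom - inter) / (denom * denom)).astype(
            np.float32))

    return Tensor(out_data, (pred,), bwd)


# ------------------------------------------------------------------ layers

class Layer:
    def params(self) -> list[Tensor]:
        return []


class Conv2d(Layer):
    def __init__(self, cin, cout, k, rng):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0, std, (cout, cin, k, k)))
        self.b = Tensor(np.zeros(cout))

    def __call__(self, x):
        return conv2d_same(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class DownConv2d(Layer):
    def __init__(self, cin, cout, rng):
        std = np.sqrt(2.0 / (cin * 4))
        self.w = Tensor(rng.normal(0, std, (cout, cin, 2, 2)))
        self.b = Tensor(np.zeros(cout))

    def __call__(self, x):
        return down_conv2x2(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class UpConv2d(Layer):
    def __init__(self, cin, cout, rng):
        std = np.sqrt(2.0 / cin)
        self.w = Tensor(rng.normal(0, std, (cin, cout, 2, 2)))
        self.b = Tensor(np.zeros(cout))

    def __call__(self, x):
        return up_conv2x2(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class BatchNorm2d(Layer):
    def __init__(self, c):
        self.gamma = Tensor(np.ones(c))
        self.beta = Tensor(np.zeros(c))
        self.running = {"mean": np.zeros(c, np.float32),
                        "var": np.ones(c, np.float32)}

    def __call__(self, x, train: bool):
        return batch_norm(x, self.gamma, self.beta, self.running, train)

    def params(self):
        return [self.gamma, self.beta]


class PReLU(Layer):
    def __init__(self, c, init=0.25):
        self.alpha = Tensor(np.full(c, init))

    def __call__(self, x):
        return prelu(x, self.alpha)

    def params(self):
        return [self.alpha]


class ConvBNAct(Layer):
    """conv -> batch norm -> PReLU (the package's stated ordering)."""

    def __init__(self, cin, cout, k, rng):
        self.conv = Conv2d(cin, cout, k, rng)
        self.bn = BatchNorm2d(cout)
        self.act = PReLU(cout)

    def __call__(self, x, train):
        return self.act(self.bn(self.conv(x), train))

    def params(self):
        return self.conv.params() + self.bn.params() + self.act.params()


class ResBlock(Layer):
    """Two conv-BN-PReLU units with an identity (or 1x1-projected) skip."""

    def __init__(self, cin, cout, k, rng):
        self.u1 = ConvBNAct(cin, cout, k, rng)
        self.u2 = ConvBNAct(cout, cout, k, rng)
        self.proj = Conv2d(cin, cout, 1, rng) if cin != cout else None

    def __call__(self, x, train):
        y = self.u2(self.u1(x, train), train)
        s = self.proj(x) if self.proj is not None else x
        return add(y, s)

    def params(self):
        out = self.u1.params() + self.u2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


# --------------------------------------------------------------- optimizer

class Adam:
    def __init__(self, params: Iterable[Tensor], lr=2e-4, beta1=0.9,
                 beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )


def parameter_count(layers: Iterable[Layer] | Iterable[Tensor]) -> int:
    total = 0
    for item in layers:
        tensors = item.params() if isinstance(item, Layer) else [item]
        for t in tensors:
            total += t.data.size
    return total
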