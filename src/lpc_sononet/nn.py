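"""Minimal seeded CNN engine on NumPy.

Implements exactly the layer vocabulary the networks in this package need:
bias-free 2-D convolution (im2col + BLAS matmul), batch normalization, ReLU,
2x2 max pooling, channel concatenation, global spatial max pooling, Adam, and
softmax cross-entropy. Forward passes cache what the backward pass needs, so a
``Model`` supports full training as well as the partial backward sweeps used
by GradCAM.

All arithmetic is float32. Given the same seed and input, instantiation and
training are bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalMaxPool",
    "ConvBNReLU",
    "LPCBlock",
    "AdaptationHead",
    "Model",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]

_F32 = np.float32


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=_F32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return int(self.data.size)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    # fan-in-scaled normal init (suits rectifier nonlinearities)
    std = np.sqrt(2.0 / fan_in)
    return rng.standard_normal(shape).astype(_F32) * _F32(std)


class Layer:
    """Base layer: forward caches, backward consumes the cache."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list:
        return []


class Conv2d(Layer):
    """Bias-free 2-D convolution, stride 1.

    Kernel 3x3 uses padding 1, kernel 1x1 padding 0, so spatial size is
    always preserved. Weight layout is (out_ch, in_ch * k * k) to keep the
    im2col matmul a single BLAS call over the whole batch.
    """

    def __init__(self, name: str, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are used here")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.pad = (kernel - 1) // 2
        fan_in = in_ch * kernel * kernel
        self.weight = Param(f"{name}.weight",
                            _he_init(rng, (out_ch, fan_in), fan_in))
        self._cache = None

    def params(self):
        return [self.weight]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        if k == 1:
            return np.ascontiguousarray(
                x.transpose(1, 0, 2, 3).reshape(c, n * h * w))
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad),
                        (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (c*k*k, n*h*w)
        cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * h * w)
        return np.ascontiguousarray(cols)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        cols = self._im2col(x)
        y = self.weight.data @ cols  # (out_ch, n*h*w)
        y = y.reshape(self.out_ch, n, h, w).transpose(1, 0, 2, 3)
        self._cache = (cols, (n, c, h, w))
        return np.ascontiguousarray(y)

    def backward(self, dy):
        cols, (n, c, h, w) = self._cache
        dyf = np.ascontiguousarray(
            dy.transpose(1, 0, 2, 3).reshape(self.out_ch, n * h * w))
        self.weight.grad += dyf @ cols.T
        dcols = self.weight.data.T @ dyf  # (c*k*k, n*h*w)
        k = self.kernel
        if k == 1:
            dx = dcols.reshape(c, n, h, w).transpose(1, 0, 2, 3)
            return np.ascontiguousarray(dx)
        dcols = dcols.reshape(c, k, k, n, h, w)
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=_F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, i, j].transpose(1, 0, 2, 3)
        return dxp[:, :, self.pad:self.pad + h, self.pad:self.pad + w]


class BatchNorm2d(Layer):
    def __init__(self, name: str, ch: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Param(f"{name}.gamma", np.ones(ch, dtype=_F32))
        self.beta = Param(f"{name}.beta", np.zeros(ch, dtype=_F32))
        self.running_mean = np.zeros(ch, dtype=_F32)
        self.running_var = np.ones(ch, dtype=_F32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(_F32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = (self.gamma.data[None, :, None, None] * xhat
             + self.beta.data[None, :, None, None])
        self._cache = (xhat, inv.astype(_F32), train, x.shape)
        return y.astype(_F32)

    def backward(self, dy):
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not train:
            return (dy * g * inv[None, :, None, None]).astype(_F32)
        n, _, h, w = shape
        m = n * h * w
        dxhat = dy * g
        dx = (dxhat
              - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return (dx * inv[None, :, None, None]).astype(_F32)


class ReLU(Layer):
    def forward(self, x, train=False):
        y = np.maximum(x, 0)
        self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; trailing odd rows/columns are dropped."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, :2 * h2, :2 * w2]
        patches = xt.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = patches.reshape(n, c, h2, w2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w))
        return np.ascontiguousarray(y)

    def backward(self, dy):
        idx, (n, c, h, w) = self._cache
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((n, c, h2, w2, 4), dtype=_F32)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=_F32)
        dx[:, :, :2 * h2, :2 * w2] = (
            dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2))
        return dx


class GlobalMaxPool(Layer):
    """Global spatial max: (N, C, H, W) -> (N, C).

    This is the implicit region-of-interest search of the adaptation head:
    the class score is the best response anywhere in the image.
    """

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, (n, c, h, w))
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        idx, (n, c, h, w) = self._cache
        dflat = np.zeros((n, c, h * w), dtype=_F32)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        return dflat.reshape(n, c, h, w)


class ConvBNReLU(Layer):
    """conv -> batch norm -> rectifier, the unit both backbones are built from."""

    def __init__(self, name, in_ch, out_ch, kernel, rng, relu=True):
        self.conv = Conv2d(name + ".conv", in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm2d(name + ".bn", out_ch)
        self.relu = ReLU() if relu else None

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=False):
        y = self.bn.forward(self.conv.forward(x, train), train)
        return self.relu.forward(y, train) if self.relu else y

    def backward(self, dy):
        if self.relu:
            dy = self.relu.backward(dy)
        return self.conv.backward(self.bn.backward(dy))


class LPCBlock(Layer):
    """Light pyramid convolution block.

    Two stacked 3x3 convolutions produce small- and large-receptive-field
    maps; both are concatenated with the input (three scales) and fused by a
    1x1 convolution. Every convolution is bias-free with batch norm and a
    rectifier; spatial size is preserved.
    """

    def __init__(self, name, in_ch, hidden_ch, out_ch, rng):
        self.in_ch, self.hidden_ch, self.out_ch = in_ch, hidden_ch, out_ch
        self.branch_a = ConvBNReLU(name + ".conv_a", in_ch, hidden_ch, 3, rng)
        self.branch_b = ConvBNReLU(name + ".conv_b", hidden_ch, hidden_ch, 3, rng)
        self.fuse = ConvBNReLU(name + ".fuse", in_ch + 2 * hidden_ch,
                               out_ch, 1, rng)

    def params(self):
        return (self.branch_a.params() + self.branch_b.params()
                + self.fuse.params())

    def forward(self, x, train=False):
        y1 = self.branch_a.forward(x, train)
        y2 = self.branch_b.forward(y1, train)
        z = np.concatenate([x, y1, y2], axis=1)
        self._splits = (x.shape[1], y1.shape[1])
        return self.fuse.forward(z, train)

    def backward(self, dy):
        dz = self.fuse.backward(dy)
        c0, c1 = self._splits
        dx = np.ascontiguousarray(dz[:, :c0])
        dy1 = np.ascontiguousarray(dz[:, c0:c0 + c1])
        dy2 = np.ascontiguousarray(dz[:, c0 + c1:])
        dy1 = dy1 + self.branch_b.backward(dy2)
        return dx + self.branch_a.backward(dy1)


class AdaptationHead(Layer):
    """Fully convolutional classifier head shared by both networks.

    1x1 conv halving the channels (norm + rectifier), 1x1 conv to K class
    channels (norm, no rectifier), then global spatial max pooling to logits.
    Accepts any spatial size, which is what makes variable-size input work.
    """

    def __init__(self, name, in_ch, mid_ch, num_classes, rng):
        self.reduce = ConvBNReLU(name + ".reduce", in_ch, mid_ch, 1, rng)
        self.classify = ConvBNReLU(name + ".classify", mid_ch, num_classes,
                                   1, rng, relu=False)
        self.pool = GlobalMaxPool()

    def params(self):
        return self.reduce.params() + self.classify.params()

    def forward(self, x, train=False):
        y = self.classify.forward(self.reduce.forward(x, train), train)
        return self.pool.forward(y, train)

    def backward(self, dy):
        return self.reduce.backward(
            self.classify.backward(self.pool.backward(dy)))


class Model:
    """An ordered pipeline of named stages ending in logits.

    ``forward_features`` stops after a named stage (used by GradCAM), and
    ``backward_to`` propagates a logit gradient back down to that stage's
    output without touching earlier stages.
    """

    def __init__(self, stages: list):
        self.stages = stages  # list of (name, Layer)
        self._names = [n for n, _ in stages]

    def params(self) -> list:
        out = []
        for _, layer in self.stages:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for _, layer in self.stages:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = dlogits
        for _, layer in reversed(self.stages):
            g = layer.backward(g)
        return g

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0

    # --- feature capture for attribution -----------------------------------
    def stage_names(self) -> list:
        return list(self._names)

    def forward_features(self, x: np.ndarray, stage: str,
                         train: bool = False):
        """Run forward, returning (logits, activation after `stage`)."""
        if stage not in self._names:
            raise ValueError(
                f"unknown stage {stage!r}; available: {self._names}")
        feat = None
        for name, layer in self.stages:
            x = layer.forward(x, train)
            if name == stage:
                feat = x
        return x, feat

    def backward_to(self, stage: str, dlogits: np.ndarray) -> np.ndarray:
        """Gradient of the logit functional w.r.t. the output of `stage`."""
        i = self._names.index(stage)
        g = dlogits
        for _, layer in reversed(self.stages[i + 1:]):
            g = layer.backward(g)
        return g

    # --- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict:
        state = {p.name: p.data.copy() for p in self.params()}
        for name, layer in self.stages:
            for sub in _iter_bn(layer):
                state[f"{sub.gamma.name[:-6]}.running_mean"] = \
                    sub.running_mean.copy()
                state[f"{sub.gamma.name[:-6]}.running_var"] = \
                    sub.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        for p in self.params():
            p.data[...] = state[p.name]
        for name, layer in self.stages:
            for sub in _iter_bn(layer):
                key = sub.gamma.name[:-6]
                sub.running_mean[...] = state[f"{key}.running_mean"]
                sub.running_var[...] = state[f"{key}.running_var"]


def _iter_bn(layer):
    if isinstance(layer, BatchNorm2d):
        yield layer
    for attr in ("conv", "bn", "branch_a", "branch_b", "fuse", "reduce",
                 "classify"):
        sub = getattr(layer, attr, None)
        if isinstance(sub, Layer):
            yield from _iter_bn(sub)
    for sub in getattr(layer, "layers", []):
        yield from _iter_bn(sub)


class Adam:
    """Adam with the standard bias correction; lr may change between steps."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr * (m / bc1)
                       / (np.sqrt(v / bc2) + self.eps)).astype(_F32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean()
    dlogits = p.astype(_F32)
    dlogits[np.arange(n), labels] -= 1
    dlogits /= _F32(n)
    return float(loss), dlogits
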