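"""Minimal numpy neural-network engine (NCHW layout).

Implements exactly the layer set the segmentation networks need: 3x3
convolution (stride 1, same padding), stride-2 transposed convolution
with Keras-style ``same``/``valid`` output sizing, batch normalization,
ReLU/sigmoid, 2x2 max-pooling, and CBAM attention (channel then spatial),
each with a hand-written backward pass, plus the Adam optimiser.

Every layer follows the same contract: ``forward(x, train)`` caches what
``backward(dy)`` needs; ``backward`` accumulates parameter gradients in
``Param.grad`` and returns the gradient with respect to the input.
Weights use He-uniform initialisation drawn from an explicit
``numpy.random.Generator``, so whole networks are reproducible from a
seed.  Activations and parameters default to float32; tests that verify
gradients analytically build layers in float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


def he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype):
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def params(self) -> list:
        return []

    def buffers(self) -> dict:
        return {}

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train)


class Conv2d(Layer):
    """3x3 (or kxk) convolution, stride 1, shape-preserving padding."""

    def __init__(self, cin: int, cout: int, k: int = 3,
                 rng: np.random.Generator | None = None,
                 dtype=None, bias: bool = True):
        dtype = dtype or DEFAULT_DTYPE
        rng = rng or np.random.default_rng(0)
        self.k = k
        self.cin, self.cout = cin, cout
        self.W = Param(he_uniform(rng, (cout, cin, k, k), cin * k * k, dtype),
                       "conv.W")
        self.b = Param(np.zeros(cout, dtype=dtype), "conv.b") if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)
        Wmat = self.W.value.reshape(self.cout, C * k * k)
        y = cols @ Wmat.T
        if self.b is not None:
            y += self.b.value
        y = y.reshape(B, H, W, self.cout).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape) if train else None
        return np.ascontiguousarray(y)

    def backward(self, dy):
        cols, xshape = self._cache
        B, C, H, W = xshape
        k, p = self.k, self.k // 2
        dym = dy.transpose(0, 2, 3, 1).reshape(B * H * W, self.cout)
        self.W.grad += (dym.T @ cols).reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += dym.sum(axis=0)
        dcols = (dym @ self.W.value.reshape(self.cout, -1))
        dcols = dcols.reshape(B, H, W, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dy.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W]


class ConvTranspose2d(Layer):
    """Stride-2 transposed convolution with Keras output sizing.

    ``padding='same'`` doubles the spatial size (out = 2*in, trailing
    row/column cropped); ``padding='valid'`` gives out = 2*in + 1 for a
    3x3 kernel.  The pair inverts the encoder's floor-halving max-pool
    chain: an even size is recovered with ``same``, an odd one with
    ``valid``.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 padding: str = "same",
                 rng: np.random.Generator | None = None, dtype=None):
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be same/valid, got {padding!r}")
        dtype = dtype or DEFAULT_DTYPE
        rng = rng or np.random.default_rng(0)
        self.k, self.s, self.padding = k, stride, padding
        self.cin, self.cout = cin, cout
        self.W = Param(he_uniform(rng, (cin, cout, k, k), cin * k * k, dtype),
                       "convT.W")
        self.b = Param(np.zeros(cout, dtype=dtype), "convT.b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_size(self, n: int) -> int:
        return self.s * n if self.padding == "same" else self.s * (n - 1) + self.k

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        k, s = self.k, self.s
        fh, fw = s * (H - 1) + k, s * (W - 1) + k
        y = np.zeros((B, self.cout, fh, fw), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                y[:, :, i:i + s * (H - 1) + 1:s, j:j + s * (W - 1) + 1:s] += \
                    np.einsum("bchw,co->bohw", x, self.W.value[:, :, i, j])
        oh, ow = self.out_size(H), self.out_size(W)
        y = y[:, :, :oh, :ow]
        y += self.b.value[None, :, None, None]
        self._cache = (x, (fh, fw)) if train else None
        return y

    def backward(self, dy):
        x, (fh, fw) = self._cache
        B, C, H, W = x.shape
        k, s = self.k, self.s
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dyf = np.zeros((B, self.cout, fh, fw), dtype=dy.dtype)
        dyf[:, :, :dy.shape[2], :dy.shape[3]] = dy
        dx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                sl = dyf[:, :, i:i + s * (H - 1) + 1:s, j:j + s * (W - 1) + 1:s]
                dx += np.einsum("bohw,co->bchw", sl, self.W.value[:, :, i, j])
                self.W.grad[:, :, i, j] += np.einsum("bchw,bohw->co", x, sl)
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.99, eps: float = 1e-3,
                 dtype=None):
        dtype = dtype or DEFAULT_DTYPE
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(c, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return {"running_mean": self.running_mean,
                "running_var": self.running_var}

    def load_buffers(self, bufs):
        self.running_mean = np.array(bufs["running_mean"])
        self.running_var = np.array(bufs["running_var"])

    def forward(self, x, train: bool = False):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(
                self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + \
            self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat, invstd, x.shape)
        return y

    def backward(self, dy):
        xhat, invstd, xshape = self._cache
        B, C, H, W = xshape
        n = B * H * W
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (invstd[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)
        return dx


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train: bool = False):
        # numerically stable two-sided formulation
        y = np.where(x >= 0,
                     1.0 / (1.0 + np.exp(-np.clip(x, 0, None))),
                     np.exp(np.clip(x, None, 0))
                     / (1.0 + np.exp(np.clip(x, None, 0))))
        if train:
            self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2, valid (floor) sizing."""

    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        k = self.k
        oh, ow = H // k, W // k
        xc = x[:, :, :oh * k, :ow * k]
        xr = xc.reshape(B, C, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(B, C, oh, ow, k * k)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, xshape = self._cache
        B, C, H, W = xshape
        k = self.k
        oh, ow = H // k, W // k
        dflat = np.zeros((B, C, oh, ow, k * k), dtype=dy.dtype)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dxc = dflat.reshape(B, C, oh, ow, k, k).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(xshape, dtype=dy.dtype)
        dx[:, :, :oh * k, :ow * k] = dxc.reshape(B, C, oh * k, ow * k)
        return dx


class ChannelAttention(Layer):
    """CBAM channel gate: shared 2-layer MLP over avg- and max-pooled maps."""

    def __init__(self, c: int, reduction: int = 16,
                 rng: np.random.Generator | None = None, dtype=None):
        dtype = dtype or DEFAULT_DTYPE
        rng = rng or np.random.default_rng(0)
        hidden = max(c // reduction, 1)
        self.W1 = Param(he_uniform(rng, (c, hidden), c, dtype), "ca.W1")
        self.W2 = Param(he_uniform(rng, (hidden, c), hidden, dtype), "ca.W2")
        self._cache = None

    def params(self):
        return [self.W1, self.W2]

    def _mlp(self, s):
        a = np.maximum(s @ self.W1.value, 0)
        return a, a @ self.W2.value

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        s_avg = x.mean(axis=(2, 3))
        flat = x.reshape(B, C, H * W)
        arg = flat.argmax(axis=-1)
        s_max = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        a1, h1 = self._mlp(s_avg)
        a2, h2 = self._mlp(s_max)
        h = h1 + h2
        g = np.where(h >= 0,
                     1.0 / (1.0 + np.exp(-np.clip(h, 0, None))),
                     np.exp(np.clip(h, None, 0))
                     / (1.0 + np.exp(np.clip(h, None, 0))))
        y = x * g[:, :, None, None]
        if train:
            self._cache = (x, s_avg, s_max, a1, a2, g, arg)
        return y

    def backward(self, dy):
        x, s_avg, s_max, a1, a2, g, arg = self._cache
        B, C, H, W = x.shape
        dx = dy * g[:, :, None, None]
        dg = (dy * x).sum(axis=(2, 3))
        dh = dg * g * (1.0 - g)
        ds = []
        for a, s in ((a1, s_avg), (a2, s_max)):
            self.W2.grad += a.T @ dh
            da = (dh @ self.W2.value.T) * (a > 0)
            self.W1.grad += s.T @ da
            ds.append(da @ self.W1.value.T)
        dx += ds[0][:, :, None, None] / (H * W)
        dmax_flat = np.zeros((B, C, H * W), dtype=dy.dtype)
        np.put_along_axis(dmax_flat, arg[..., None], ds[1][..., None], axis=-1)
        dx += dmax_flat.reshape(B, C, H, W)
        return dx


class SpatialAttention(Layer):
    """CBAM spatial gate: 7x7 conv over stacked channel-mean/max maps."""

    def __init__(self, k: int = 7, rng: np.random.Generator | None = None,
                 dtype=None):
        self.conv = Conv2d(2, 1, k=k, rng=rng, dtype=dtype)
        self.sig = Sigmoid()
        self._cache = None

    def params(self):
        return self.conv.params()

    def forward(self, x, train: bool = False):
        B, C, H, W = x.shape
        f_avg = x.mean(axis=1, keepdims=True)
        arg = x.argmax(axis=1, keepdims=True)
        f_max = np.take_along_axis(x, arg, axis=1)
        f = np.concatenate([f_avg, f_max], axis=1)
        m = self.sig.forward(self.conv.forward(f, train), train)
        y = x * m
        if train:
            self._cache = (x, m, arg, C)
        return y

    def backward(self, dy):
        x, m, arg, C = self._cache
        dx = dy * m
        dm = (dy * x).sum(axis=1, keepdims=True)
        df = self.conv.backward(self.sig.backward(dm))
        dx += df[:, 0:1, :, :] / C
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, arg, df[:, 1:2, :, :], axis=1)
        return dx + dmax


class CBAM(Layer):
    """Channel-then-spatial attention."""

    def __init__(self, c: int, reduction: int = 16, spatial_k: int = 7,
                 rng: np.random.Generator | None = None, dtype=None):
        self.channel = ChannelAttention(c, reduction, rng=rng, dtype=dtype)
        self.spatial = SpatialAttention(spatial_k, rng=rng, dtype=dtype)

    def params(self):
        return self.channel.params() + self.spatial.params()

    def forward(self, x, train: bool = False):
        return self.spatial.forward(self.channel.forward(x, train), train)

    def backward(self, dy):
        return self.channel.backward(self.spatial.backward(dy))


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, train: bool = False):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def iter_modules(self):
        for lay in self.layers:
            if isinstance(lay, Sequential):
                yield from lay.iter_modules()
            else:
                yield lay


class Adam:
    """Adam optimiser (betas 0.9/0.999, Keras-style epsilon 1e-7)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
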