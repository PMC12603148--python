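"""Hand-written neural-network layers (forward + reverse-mode backward).

Conventions
-----------
* 3D tensors: (B, C, D, H, W); 2D tensors: (B, C, H, W); dense: (B, F).
* Each layer caches what its backward pass needs during forward; backward
  consumes the upstream gradient and accumulates into ``Param.grad``.
* Parameters default to float32; computation follows the input dtype, so
  gradient checks can run the same layers in float64.
"""

from __future__ import annotations

import itertools

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Module:
    """Base class: a tree of sub-modules and parameters."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def state(self) -> list[np.ndarray]:
        """Snapshot of all parameter arrays (copies), plus batch-norm stats."""
        arrs = [p.data.copy() for p in self.params()]
        arrs += [b.copy() for b in self._buffers()]
        return arrs

    def load_state(self, arrs: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrs[: len(ps)]):
            p.data = a.copy()
        bufs = self._buffers()
        for i, a in enumerate(arrs[len(ps):]):
            bufs[i][...] = a

    def _buffers(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, BatchNorm):
                out += [v.running_mean, v.running_var]
            elif isinstance(v, Module):
                out.extend(v._buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item._buffers())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train)


# --------------------------------------------------------------------------
# elementary layers
# --------------------------------------------------------------------------


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Sigmoid(Module):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Dense(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Param(_he_init(rng, (nin, nout), nin, dtype))
        self.b = Param(np.zeros(nout, dtype))

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, gy):
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.data.T


class Dropout(Module):
    """Inverted dropout; identity in eval mode. ``rng`` is set by the trainer."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout p must be in [0,1), got {p}")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, train=True):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Flatten(Module):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class BatchNorm(Module):
    """Batch normalization over (batch, spatial) per channel, any spatial rank."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype))
        self.beta = Param(np.zeros(channels, dtype))
        self.running_mean = np.zeros(channels, dtype)
        self.running_var = np.ones(channels, dtype)
        self.eps = eps
        self.momentum = momentum

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, train=True):
        axes = (0,) + tuple(range(2, x.ndim))
        bs = self._bshape(x.ndim)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(bs)) / std.reshape(bs)
        self._cache = (xhat, std, axes, bs, train)
        return self.gamma.data.reshape(bs) * xhat + self.beta.data.reshape(bs)

    def backward(self, gy):
        xhat, std, axes, bs, trained = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = gy * self.gamma.data.reshape(bs)
        if not trained:
            return g / std.reshape(bs)
        n = gy.size // gy.shape[1]
        gsum = g.sum(axis=axes).reshape(bs)
        gxhat_sum = (g * xhat).sum(axis=axes).reshape(bs)
        return (g - gsum / n - xhat * gxhat_sum / n) / std.reshape(bs)


# --------------------------------------------------------------------------
# convolutions
# --------------------------------------------------------------------------


class Conv3d(Module):
    """3D convolution, stride 1, 'same' padding by default (k odd)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 pad: int | None = None, dtype=np.float32):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = (k // 2) if pad is None else pad
        fan_in = cin * k ** 3
        self.W = Param(_he_init(rng, (fan_in, cout), fan_in, dtype))
        self.b = Param(np.zeros(cout, dtype))

    def forward(self, x, train=True):
        B, C, D, H, W = x.shape
        k, p = self.k, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
        Do, Ho, Wo = win.shape[2:5]
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            B * Do * Ho * Wo, C * k ** 3
        )
        y = col @ self.W.data + self.b.data
        self._cache = (col, (B, C, D, H, W), (Do, Ho, Wo))
        return y.reshape(B, Do, Ho, Wo, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, gy):
        col, (B, C, D, H, W), (Do, Ho, Wo) = self._cache
        k, p = self.k, self.pad
        gy2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cout)
        self.W.grad += col.T @ gy2
        self.b.grad += gy2.sum(axis=0)
        gcol = (gy2 @ self.W.data.T).reshape(B, Do, Ho, Wo, C, k, k, k)
        gcol = gcol.transpose(0, 4, 1, 2, 3, 5, 6, 7)  # (B,C,Do,Ho,Wo,k,k,k)
        gxp = np.zeros((B, C, D + 2 * p, H + 2 * p, W + 2 * p), dtype=gy.dtype)
        for i, j, l in itertools.product(range(k), range(k), range(k)):
            gxp[:, :, i:i + Do, j:j + Ho, l:l + Wo] += gcol[..., i, j, l]
        return gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp


class Conv2d(Module):
    """2D convolution with stride; 'same' padding by default (k odd, stride 1)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, dtype=np.float32):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = cin * k ** 2
        self.W = Param(_he_init(rng, (fan_in, cout), fan_in, dtype))
        self.b = Param(np.zeros(cout, dtype))

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        k, p, s = self.k, self.pad, self.stride
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        Ho, Wo = win.shape[2:4]
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * Ho * Wo, C * k ** 2
        )
        y = col @ self.W.data + self.b.data
        self._cache = (col, (B, C, H, W), (Ho, Wo))
        return y.reshape(B, Ho, Wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gy):
        col, (B, C, H, W), (Ho, Wo) = self._cache
        k, p, s = self.k, self.pad, self.stride
        gy2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.W.grad += col.T @ gy2
        self.b.grad += gy2.sum(axis=0)
        gcol = (gy2 @ self.W.data.T).reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=gy.dtype)
        for i, j in itertools.product(range(k), range(k)):
            gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += gcol[..., i, j]
        return gxp[:, :, p:p + H, p:p + W] if p else gxp


class ConvTranspose3d(Module):
    """Transposed 3D convolution, kernel 2, stride 2 (non-overlapping upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.cin, self.cout = cin, cout
        self.W = Param(_he_init(rng, (cin, cout, 2, 2, 2), cin, dtype))
        self.b = Param(np.zeros(cout, dtype))

    def forward(self, x, train=True):
        self._x = x
        B, C, D, H, W = x.shape
        y = np.einsum("bcdhw,coijk->bodihjwk", x, self.W.data, optimize=True)
        y = y.reshape(B, self.cout, 2 * D, 2 * H, 2 * W)
        return y + self.b.data.reshape(1, -1, 1, 1, 1)

    def backward(self, gy):
        x = self._x
        B, C, D, H, W = x.shape
        g = gy.reshape(B, self.cout, D, 2, H, 2, W, 2)
        self.W.grad += np.einsum("bcdhw,bodihjwk->coijk", x, g, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2, 3, 4))
        return np.einsum("bodihjwk,coijk->bcdhw", g, self.W.data, optimize=True)


# --------------------------------------------------------------------------
# pooling
# --------------------------------------------------------------------------


class MaxPool3d(Module):
    """2x2x2 max pooling; input spatial dims must be even."""

    def forward(self, x, train=True):
        B, C, D, H, W = x.shape
        r = x.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
        r = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 6, 3, 5, 7)).reshape(
            B, C, D // 2, H // 2, W // 2, 8
        )
        self._idx = r.argmax(axis=-1)
        self._shape = (B, C, D, H, W)
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        B, C, D, H, W = self._shape
        g = np.zeros((B, C, D // 2, H // 2, W // 2, 8), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return g.reshape(B, C, D, H, W)


class MaxPool2d(Module):
    """2x2 max pooling; input spatial dims must be even."""

    def forward(self, x, train=True):
        B, C, H, W = x.shape
        r = x.reshape(B, C, H // 2, 2, W // 2, 2)
        r = np.ascontiguousarray(r.transpose(0, 1, 2, 4, 3, 5)).reshape(B, C, H // 2, W // 2, 4)
        self._idx = r.argmax(axis=-1)
        self._shape = (B, C, H, W)
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        B, C, H, W = self._shape
        g = np.zeros((B, C, H // 2, W // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g, self._idx[..., None], gy[..., None], axis=-1)
        g = g.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(B, C, H, W)


class GlobalAvgPool2d(Module):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy):
        B, C, H, W = self._shape
        return np.broadcast_to(gy[:, :, None, None], self._shape) / (H * W)


# --------------------------------------------------------------------------
# composite blocks
# --------------------------------------------------------------------------


class SqueezeExcite3d(Module):
    """Channel attention: global average pool -> bottleneck MLP -> sigmoid gate."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4,
                 dtype=np.float32):
        hidden = max(1, channels // reduction)
        self.fc1 = Dense(channels, hidden, rng, dtype)
        self.fc2 = Dense(hidden, channels, rng, dtype)

    def forward(self, x, train=True):
        s = x.mean(axis=(2, 3, 4))                      # (B, C)
        z = self.fc1.forward(s, train)
        zr = z * (z > 0)
        a = self.fc2.forward(zr, train)
        g = 1.0 / (1.0 + np.exp(-a))
        self._cache = (x, z, g)
        return x * g[:, :, None, None, None]

    def backward(self, gy):
        x, z, g = self._cache
        gg = (gy * x).sum(axis=(2, 3, 4))
        gx = gy * g[:, :, None, None, None]
        ga = gg * g * (1.0 - g)
        gzr = self.fc2.backward(ga)
        gz = gzr * (z > 0)
        gs = self.fc1.backward(gz)
        n = x.shape[2] * x.shape[3] * x.shape[4]
        return gx + gs[:, :, None, None, None] / n


class ConvBlock3d(Module):
    """conv3-BN-ReLU x2 with optional identity/projection residual shortcut."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 residual: bool = False, dtype=np.float32):
        self.conv1 = Conv3d(cin, cout, 3, rng, dtype=dtype)
        self.bn1 = BatchNorm(cout, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, 3, rng, dtype=dtype)
        self.bn2 = BatchNorm(cout, dtype=dtype)
        self.relu2 = ReLU()
        self.residual = residual
        self.short = None
        if residual and cin != cout:
            self.short = Conv3d(cin, cout, 1, rng, pad=0, dtype=dtype)

    def forward(self, x, train=True):
        h = self.bn1.forward(self.conv1.forward(x, train), train)
        h = self.relu1.forward(h, train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        if self.residual:
            h = h + (self.short.forward(x, train) if self.short is not None else x)
        return self.relu2.forward(h, train)

    def backward(self, gy):
        g = self.relu2.backward(gy)
        gskip = None
        if self.residual:
            gskip = self.short.backward(g) if self.short is not None else g
        g = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))))
        if gskip is not None:
            g = g + gskip
        return g


class ResBlock2d(Module):
    """Standard 2-conv residual block with optional downsampling stride."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride, dtype=dtype)
        self.bn1 = BatchNorm(cout, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng, dtype=dtype)
        self.bn2 = BatchNorm(cout, dtype=dtype)
        self.relu2 = ReLU()
        self.short = None
        if stride != 1 or cin != cout:
            self.short = Sequential(
                Conv2d(cin, cout, 1, rng, stride=stride, pad=0, dtype=dtype),
                BatchNorm(cout, dtype=dtype),
            )

    def forward(self, x, train=True):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        h = h + (self.short.forward(x, train) if self.short is not None else x)
        return self.relu2.forward(h, train)

    def backward(self, gy):
        g = self.relu2.backward(gy)
        gskip = self.short.backward(g) if self.short is not None else g
        g = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(g)))))
        return g + gskip
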