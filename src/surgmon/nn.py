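"""Minimal NumPy neural-network engine.

Implements exactly the layer vocabulary needed by the two monitoring
architectures (an InceptionV3-style classifier and an scSE-FC-DenseNet
segmenter): convolutions (valid / same / transposed), pooling, dense
blocks, squeeze-and-excitation gating, fully connected heads, and the
two optimizers used for training (momentum SGD and AdaBound).

All image tensors are NHWC ``float32`` / ``float64`` arrays; every layer
provides an explicit ``forward``/``backward`` pair, and trainable arrays
are exposed through :class:`Param` so optimizers and parameter counters
can walk them uniformly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """One trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base class: stateless layers may skip overriding ``params``."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------

class Conv2D(Layer):
    """2-D convolution on NHWC tensors.

    ``padding='valid'`` uses out = floor((in - k)/stride) + 1 per spatial
    axis; ``padding='same'`` (stride 1 only) preserves spatial dims.
    Weight shape is (kh, kw, cin, cout) with one bias per output channel.
    """

    def __init__(self, kh: int, kw: int, cin: int, cout: int, stride: int = 1,
                 padding: str = "valid", rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        if min(kh, kw, cin, cout, stride) < 1:
            raise ValueError("conv dimensions and stride must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        self.stride = stride
        self.padding = padding
        self.w = Param(_he_init(rng, (kh, kw, cin, cout), kh * kw * cin), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=np.float32), f"{name}.b")
        self._cache = None

    def _pad_amounts(self) -> tuple[int, int, int, int]:
        if self.padding == "valid":
            return 0, 0, 0, 0
        # 'same' with stride 1: total pad = k - 1, split floor/ceil
        pt = (self.kh - 1) // 2
        pl = (self.kw - 1) // 2
        return pt, self.kh - 1 - pt, pl, self.kw - 1 - pl

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        pt, pb, pl, pr = self._pad_amounts()
        oh = (h + pt + pb - self.kh) // self.stride + 1
        ow = (w + pl + pr - self.kw) // self.stride + 1
        if oh < 1 or ow < 1:
            raise ValueError("convolution output dimension < 1")
        return oh, ow

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        pt, pb, pl, pr = self._pad_amounts()
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))) if (pt or pb or pl or pr) else x
        oh, ow = self.out_shape(h, w)
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        win = win[:, :: self.stride, :: self.stride]          # (n, oh, ow, c, kh, kw)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
        cols = cols.reshape(n, oh, ow, self.kh * self.kw * c)
        wmat = self.w.value.reshape(self.kh * self.kw * self.cin, self.cout)
        y = cols @ wmat + self.b.value
        if train:
            self._cache = (cols, xp.shape, (n, h, w, c))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, x_shape = self._cache
        n, oh, ow, _ = dy.shape
        dyf = dy.reshape(-1, self.cout)
        colsf = cols.reshape(-1, cols.shape[-1])
        self.w.grad += (colsf.T @ dyf).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=0)
        wmat = self.w.value.reshape(-1, self.cout)
        dcols = (dyf @ wmat.T).reshape(n, oh, ow, self.kh, self.kw, self.cin)
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        s = self.stride
        for di in range(self.kh):
            for dj in range(self.kw):
                dxp[:, di: di + s * oh: s, dj: dj + s * ow: s, :] += dcols[:, :, :, di, dj, :]
        pt, pb, pl, pr = self._pad_amounts()
        _, h, w, _ = x_shape
        return dxp[:, pt: pt + h, pl: pl + w, :]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ConvTranspose2D(Layer):
    """Stride-2 transposed convolution that exactly doubles spatial dims.

    Equivalent to a 3x3/2 transposed conv with symmetric padding 1 and
    output padding 1 (the FC-DenseNet transition-up).
    """

    def __init__(self, k: int, cin: int, cout: int, stride: int = 2,
                 rng: np.random.Generator | None = None, name: str = "tconv") -> None:
        if stride != 2:
            raise ValueError("only the doubling stride-2 transition-up is supported")
        rng = rng or np.random.default_rng(0)
        self.k, self.cin, self.cout, self.stride = k, cin, cout, stride
        self.w = Param(_he_init(rng, (k, k, cin, cout), cin), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=np.float32), f"{name}.b")
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        pad = (self.k - 1) // 2
        oh, ow = 2 * h, 2 * w
        yp = np.zeros((n, oh + 2 * pad, ow + 2 * pad, self.cout), dtype=x.dtype)
        xf = x.reshape(-1, c)
        for di in range(self.k):
            for dj in range(self.k):
                contrib = (xf @ self.w.value[di, dj]).reshape(n, h, w, self.cout)
                yp[:, di: di + 2 * h: 2, dj: dj + 2 * w: 2, :] += contrib
        y = yp[:, pad: pad + oh, pad: pad + ow, :] + self.b.value
        if train:
            self._cache = (x, yp.shape, pad)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, yp_shape, pad = self._cache
        n, h, w, _ = x.shape
        dyp = np.zeros(yp_shape, dtype=dy.dtype)
        dyp[:, pad: pad + dy.shape[1], pad: pad + dy.shape[2], :] = dy
        self.b.grad += dy.sum(axis=(0, 1, 2))
        xf = x.reshape(-1, self.cin)
        dx = np.zeros_like(x)
        for di in range(self.k):
            for dj in range(self.k):
                sl = dyp[:, di: di + 2 * h: 2, dj: dj + 2 * w: 2, :].reshape(-1, self.cout)
                self.w.grad[di, dj] += xf.T @ sl
                dx += (sl @ self.w.value[di, dj].T).reshape(n, h, w, self.cin)
        return dx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class MaxPool2D(Layer):
    def __init__(self, k: int = 3, stride: int = 2, padding: str = "valid") -> None:
        self.k, self.stride, self.padding = k, stride, padding
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if self.padding == "same":
            pt = (self.k - 1) // 2
            x = np.pad(x, ((0, 0), (pt, self.k - 1 - pt), (pt, self.k - 1 - pt), (0, 0)),
                       constant_values=-np.inf)
            h, w = x.shape[1], x.shape[2]
        oh = (h - self.k) // self.stride + 1
        ow = (w - self.k) // self.stride + 1
        win = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        win = win[:, :: self.stride, :: self.stride]          # (n,oh,ow,c,k,k)
        flat = win.reshape(n, oh, ow, c, self.k * self.k)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape, (oh, ow))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, xp_shape, (oh, ow) = self._cache
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        s = self.stride
        for f in range(self.k * self.k):
            di, dj = divmod(f, self.k)
            mask = (idx == f)
            dxp[:, di: di + s * oh: s, dj: dj + s * ow: s, :] += np.where(mask, dy, 0.0)
        if self.padding == "same":
            pt = (self.k - 1) // 2
            h = xp_shape[1] - (self.k - 1)
            w = xp_shape[2] - (self.k - 1)
            return dxp[:, pt: pt + h, pt: pt + w, :]
        return dxp

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        if self.padding == "same":
            return (h - 1) // self.stride + 1, (w - 1) // self.stride + 1
        return (h - self.k) // self.stride + 1, (w - self.k) // self.stride + 1


class AvgPool2D(Layer):
    """Stride-1 'same' average pooling (used inside Inception branches)."""

    def __init__(self, k: int = 3) -> None:
        self.k = k
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pt = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (pt, self.k - 1 - pt), (pt, self.k - 1 - pt), (0, 0)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        y = win.mean(axis=(-2, -1))
        if train:
            self._cache = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape = self._cache
        pt = (self.k - 1) // 2
        n, h, w, c = x_shape
        dxp = np.zeros((n, h + self.k - 1, w + self.k - 1, c), dtype=dy.dtype)
        g = dy / (self.k * self.k)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, di: di + h, dj: dj + w, :] += g
        return dxp[:, pt: pt + h, pt: pt + w, :]


class GlobalAvgPool(Layer):
    """Averages over all spatial positions -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :], self._shape) / (h * w)


# ---------------------------------------------------------------------------
# normalization / dense / activations
# ---------------------------------------------------------------------------

class BatchNorm2D(Layer):
    # momentum 0.8 lets the running statistics track the batch statistics
    # within the few dozen steps a small CPU run takes
    def __init__(self, channels: int, momentum: float = 0.8, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels, dtype=np.float32), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[1] * shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        return (inv / m) * (m * dxhat - dxhat.sum(axis=(0, 1, 2))
                            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2)))

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 name: str = "fc") -> None:
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (d_in, d_out), d_in), f"{name}.w")
        self.b = Param(np.zeros(d_out, dtype=np.float32), f"{name}.b")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class Parallel(Layer):
    """Runs branches on the same input and concatenates along channels."""

    def __init__(self, branches: list[Layer]) -> None:
        self.branches = list(branches)
        self._splits: list[int] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = [b.forward(x, train=train) for b in self.branches]
        self._splits = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = None
        ofs = 0
        for b, width in zip(self.branches, self._splits):
            g = b.backward(dy[..., ofs: ofs + width])
            dx = g if dx is None else dx + g
            ofs += width
        return dx

    def params(self) -> list[Param]:
        out: list[Param] = []
        for b in self.branches:
            out.extend(b.params())
        return out


# ---------------------------------------------------------------------------
# attention / dense-block composites
# ---------------------------------------------------------------------------

class SCSEModule(Layer):
    """Concurrent spatial & channel squeeze-and-excitation gate.

    cSE path: global-average squeeze -> bottleneck FC (reduction r) ->
    per-channel sigmoid gate. sSE path: 1x1 conv to one map -> per-pixel
    sigmoid gate. The two gated tensors are fused elementwise; ``fusion``
    is "max" (default) or "add".
    """

    def __init__(self, channels: int, reduction: int = 2, fusion: str = "max",
                 rng: np.random.Generator | None = None, name: str = "scse") -> None:
        if channels % reduction != 0:
            raise ValueError("reduction must divide the channel count")
        if fusion not in ("max", "add"):
            raise ValueError("fusion must be 'max' or 'add'")
        rng = rng or np.random.default_rng(0)
        self.channels, self.reduction, self.fusion = channels, reduction, fusion
        self.fc1 = Dense(channels, channels // reduction, rng, f"{name}.fc1")
        self.fc2 = Dense(channels // reduction, channels, rng, f"{name}.fc2")
        self.conv = Conv2D(1, 1, channels, 1, rng=rng, name=f"{name}.spatial")
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        z = x.mean(axis=(1, 2))                                  # (n, c)
        a1 = self.fc1.forward(z, train=train)
        r1 = np.maximum(a1, 0.0)
        a2 = self.fc2.forward(r1, train=train)
        gc = 1.0 / (1.0 + np.exp(-np.clip(a2, -60, 60)))         # channel gate
        s = self.conv.forward(x, train=train)                    # (n,h,w,1)
        gs = 1.0 / (1.0 + np.exp(-np.clip(s, -60, 60)))          # spatial gate
        yc = x * gc[:, None, None, :]
        ys = x * gs
        if self.fusion == "max":
            mask = yc >= ys
            y = np.where(mask, yc, ys)
        else:
            mask = None
            y = yc + ys
        if train:
            self._cache = (x, gc, gs, a1, mask, (h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, gc, gs, a1, mask, (h, w) = self._cache
        if self.fusion == "max":
            dyc = np.where(mask, dy, 0.0)
            dys = dy - dyc
        else:
            dyc = dys = dy
        # spatial path: ys = x * gs
        dgs = (dys * x).sum(axis=-1, keepdims=True)
        ds = dgs * gs * (1.0 - gs)
        dx = dys * gs + self.conv.backward(ds)
        # channel path: yc = x * gc, gc from GAP -> fc1 -> relu -> fc2 -> sigmoid
        dgc = (dyc * x).sum(axis=(1, 2))
        da2 = dgc * gc * (1.0 - gc)
        dr1 = self.fc2.backward(da2)
        da1 = dr1 * (a1 > 0)
        dz = self.fc1.backward(da1)
        dx += dyc * gc[:, None, None, :]
        dx += np.broadcast_to(dz[:, None, None, :], x.shape) / (h * w)
        return dx

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params() + self.conv.params()


class DenseUnit(Layer):
    """One dense-block layer: concat(x, conv(relu(bn(x)))) adding ``growth`` channels."""

    def __init__(self, cin: int, growth: int, rng: np.random.Generator | None = None,
                 name: str = "dense") -> None:
        self.cin, self.growth = cin, growth
        self.f = Sequential([
            BatchNorm2D(cin, name=f"{name}.bn"),
            ReLU(),
            Conv2D(3, 3, cin, growth, stride=1, padding="same", rng=rng, name=f"{name}.conv"),
        ])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        new = self.f.forward(x, train=train)
        return np.concatenate([x, new], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx, dnew = dy[..., : self.cin], dy[..., self.cin:]
        return dx + self.f.backward(dnew)

    def params(self) -> list[Param]:
        return self.f.params()


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, d / n


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements; returns (loss, dpred)."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, 2.0 * diff / diff.size


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class SGDMomentum:
    def __init__(self, params: list[Param], lr: float = 1e-4, momentum: float = 0.9) -> None:
        self.params = params
        self.lr, self.momentum = lr, momentum
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class AdaBound:
    """Adam with element-wise learning-rate bounds converging to ``final_lr``."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999),
                 final_lr: float = 0.1, gamma: float = 1e-3, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.betas = lr, betas
        self.final_lr, self.gamma, self.eps = final_lr, gamma, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bias1 = 1 - b1 ** self._t
        bias2 = 1 - b2 ** self._t
        lo = self.final_lr * (1 - 1 / (self.gamma * self._t + 1))
        hi = self.final_lr * (1 + 1 / (self.gamma * self._t))
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            step_size = self.lr * np.sqrt(bias2) / bias1
            eta = np.clip(step_size / (np.sqrt(v) + self.eps), lo, hi)
            p.value -= eta * m
        return None

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def count_params(layer: Layer) -> int:
    """Total trainable scalars reachable from ``layer``."""
    return sum(p.size for p in layer.params())
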