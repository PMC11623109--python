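"""Layers of the NumPy CNN engine.

Conventions: inputs/outputs are ``float32`` NCHW arrays; spatial padding is
"same"; pooling and upsampling work on even spatial dims only (enforced by
the divisible-by-16 input contract upstream).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    # split by sign for numerical stability at large |x|
    out = np.empty_like(x, dtype=DTYPE)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Parameter:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()


class Conv2d(Layer):
    """2-D convolution, kernel 1x1 or 3x3, stride 1, same padding."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, *,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        if ksize not in (1, 3):
            raise ValueError(f"unsupported kernel size {ksize}")
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * ksize * ksize
        std = np.sqrt(2.0 / fan_in)  # He init, ReLU downstream
        self.w = Parameter(
            rng.normal(0.0, std, size=(out_ch, in_ch, ksize, ksize)),
            name=f"{name}.w")
        self.b = Parameter(np.zeros(out_ch), name=f"{name}.b") if bias else None
        self.ksize = ksize
        self.in_ch, self.out_ch = in_ch, out_ch
        self._x = None

    def params(self) -> list[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])

    @property
    def n_params(self) -> int:
        return self.w.data.size + (self.b.data.size if self.b is not None else 0)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected {self.in_ch} input channels, got {x.shape[1]}")
        n, _, h, w = x.shape
        if self.ksize == 1:
            self._x = x
            out = np.tensordot(x, self.w.data[:, :, 0, 0], axes=([1], [1]))
            out = out.transpose(0, 3, 1, 2)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            self._x = xp
            acc = np.zeros((n, h, w, self.out_ch), dtype=DTYPE)
            for di in range(3):
                for dj in range(3):
                    acc += np.tensordot(
                        xp[:, :, di:di + h, dj:dj + w],
                        self.w.data[:, :, di, dj], axes=([1], [1]))
            out = acc.transpose(0, 3, 1, 2)
        if self.b is not None:
            out = out + self.b.data[None, :, None, None]
        return np.ascontiguousarray(out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, _, h, w = g.shape
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2, 3))
        gn = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # N,H,W,O
        if self.ksize == 1:
            x = self._x
            self.w.grad[:, :, 0, 0] += np.tensordot(
                gn, x, axes=([0, 1, 2], [0, 2, 3]))
            dx = np.tensordot(gn, self.w.data[:, :, 0, 0], axes=([3], [0]))
            return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))
        xp = self._x
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                self.w.grad[:, :, di, dj] += np.tensordot(
                    gn, xp[:, :, di:di + h, dj:dj + w],
                    axes=([0, 1, 2], [0, 2, 3]))
                dxp[:, :, di:di + h, dj:dj + w] += np.tensordot(
                    gn, self.w.data[:, :, di, dj],
                    axes=([3], [0])).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dxp[:, :, 1:h + 1, 1:w + 1])


class BatchNorm2d(Layer):
    def __init__(self, ch: int, *, eps: float = 1e-5, momentum: float = 0.1,
                 name: str = "bn"):
        self.gamma = Parameter(np.ones(ch), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(ch), name=f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    @property
    def n_params(self) -> int:
        return self.gamma.data.size + self.beta.data.size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var
                                + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape) if train else None
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n_el = shape[0] * shape[2] * shape[3]
        self.beta.grad += g.sum(axis=(0, 2, 3))
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        gxhat = g * self.gamma.data[None, :, None, None]
        # standard batch-norm backward, reduced over N,H,W per channel
        t1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (gxhat - t1 / n_el - xhat * t2 / n_el) * \
            inv[None, :, None, None]
        return dx.astype(DTYPE)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0).astype(DTYPE)


class MaxPool2x2(Layer):
    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max-pool needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(
            xr, self._idx[..., None], axis=-1)[..., 0].astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(flat, self._idx[..., None], g[..., None], axis=-1)
        flat = flat.reshape(n, c, h // 2, w // 2, 2, 2)
        return flat.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


_BILINEAR_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(h: int) -> np.ndarray:
    """(2h, h) bilinear interpolation matrix, align_corners=False."""
    m = _BILINEAR_CACHE.get(h)
    if m is None:
        m = np.zeros((2 * h, h), dtype=DTYPE)
        for i in range(2 * h):
            s = np.clip((i + 0.5) / 2.0 - 0.5, 0.0, h - 1.0)
            i0 = int(np.floor(s))
            i1 = min(i0 + 1, h - 1)
            t = s - i0
            m[i, i0] += 1.0 - t
            m[i, i1] += t
        _BILINEAR_CACHE[h] = m
    return m


class BilinearUpsample2x(Layer):
    """Parameter-free 2x bilinear upsampling (exact transpose backward)."""

    def __init__(self):
        self._hw = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        _, _, h, w = x.shape
        self._hw = (h, w)
        mh, mw = _upsample_matrix(h), _upsample_matrix(w)
        y = np.einsum("ph,nchw->ncpw", mh, x)
        return np.einsum("qw,ncpw->ncpq", mw, y).astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        h, w = self._hw
        mh, mw = _upsample_matrix(h), _upsample_matrix(w)
        t = np.einsum("qw,ncpq->ncpw", mw, g)
        return np.einsum("ph,ncpw->nchw", mh, t).astype(DTYPE)


class AttentionGate(Layer):
    """Soft gate fusing an encoder feature with a decoder feature.

    z = Conv1x1(x) projects the encoder feature to ``inter`` channels
    (bias-free); the channel mean of z through a sigmoid yields a per-pixel
    scalar gate a; the output is the convex combination
    a*x + (1-a)*x_up, so every output element lies between the two inputs.
    """

    def __init__(self, channels: int, inter: int = 32, *,
                 rng: np.random.Generator | None = None, name: str = "gate"):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / channels)
        self.w = Parameter(rng.normal(0.0, std, size=(inter, channels)),
                           name=f"{name}.w")
        self.channels = channels
        self.inter = inter
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.w]

    @property
    def n_params(self) -> int:
        return self.w.data.size

    def forward(self, x: np.ndarray, x_up: np.ndarray,
                train: bool = True) -> np.ndarray:
        if x.shape != x_up.shape:
            raise ValueError(
                f"gate inputs must match: {x.shape} vs {x_up.shape}")
        z = np.tensordot(x, self.w.data, axes=([1], [1]))  # N,H,W,inter
        a = sigmoid(z.mean(axis=-1))[:, None]              # N,1,H,W
        self._cache = (x, x_up, a)
        return (a * x + (1.0 - a) * x_up).astype(DTYPE)

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x, x_up, a = self._cache
        da = (g * (x - x_up)).sum(axis=1)          # N,H,W
        dm = da * (a * (1.0 - a))[:, 0]            # sigmoid'
        dz = np.repeat(dm[..., None] / self.inter, self.inter, axis=-1)
        self.w.grad += np.tensordot(dz, x, axes=([0, 1, 2], [0, 2, 3]))
        dx_gate = np.tensordot(dz, self.w.data, axes=([3], [0]))
        dx = (a * g).astype(DTYPE) + \
            dx_gate.transpose(0, 3, 1, 2).astype(DTYPE)
        dx_up = ((1.0 - a) * g).astype(DTYPE)
        return dx, dx_up


class _ConvBnRelu(Layer):
    def __init__(self, in_ch, out_ch, ksize, rng, name):
        self.conv = Conv2d(in_ch, out_ch, ksize, rng=rng, name=name)
        self.bn = BatchNorm2d(out_ch, name=f"{name}.bn")
        self.act = ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    @property
    def n_params(self) -> int:
        return self.conv.n_params + self.bn.n_params

    def forward(self, x, train=True):
        return self.act.forward(
            self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.bn.backward(self.act.backward(g)))


class MultiResBlock(Layer):
    """Multi-resolution residual block.

    Three serial 3x3 conv-BN-ReLU sub-blocks whose outputs (at effective
    receptive fields 3, 5 and 7) are concatenated to ``out_ch`` channels,
    with the filter budget split in equal thirds (remainder to the last
    sub-block), plus a residual branch H(x): a 1x1 conv-BN projection, or
    the identity when ``shortcut='identity'`` and channel counts agree.
    Output is the plain sum of the concatenation and the residual branch.
    """

    def __init__(self, in_ch: int, out_ch: int, *,
                 shortcut: str = "conv",
                 rng: np.random.Generator | None = None, name: str = "mrb"):
        rng = rng or np.random.default_rng(0)
        if out_ch < 3:
            raise ValueError("multi-res block needs >= 3 output channels "
                             "(one per serial sub-block)")
        f1 = out_ch // 3
        f2 = out_ch // 3
        f3 = out_ch - f1 - f2
        self.splits = (f1, f2, f3)
        self.sub1 = _ConvBnRelu(in_ch, f1, 3, rng, f"{name}.sub1")
        self.sub2 = _ConvBnRelu(f1, f2, 3, rng, f"{name}.sub2")
        self.sub3 = _ConvBnRelu(f2, f3, 3, rng, f"{name}.sub3")
        if shortcut == "identity":
            if in_ch != out_ch:
                raise ValueError("identity shortcut needs in_ch == out_ch")
            self.short_conv = None
            self.short_bn = None
        else:
            self.short_conv = Conv2d(in_ch, out_ch, 1, rng=rng,
                                     name=f"{name}.short")
            self.short_bn = BatchNorm2d(out_ch, name=f"{name}.short.bn")
        self.in_ch, self.out_ch = in_ch, out_ch

    def params(self):
        ps = (self.sub1.params() + self.sub2.params() + self.sub3.params())
        if self.short_conv is not None:
            ps += self.short_conv.params() + self.short_bn.params()
        return ps

    @property
    def n_params(self) -> int:
        n = self.sub1.n_params + self.sub2.n_params + self.sub3.n_params
        if self.short_conv is not None:
            n += self.short_conv.n_params + self.short_bn.n_params
        return n

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(
                f"expected {self.in_ch} input channels, got {x.shape[1]}")
        o1 = self.sub1.forward(x, train)
        o2 = self.sub2.forward(o1, train)
        o3 = self.sub3.forward(o2, train)
        path = np.concatenate([o1, o2, o3], axis=1)
        if self.short_conv is None:
            res = x
        else:
            res = self.short_bn.forward(
                self.short_conv.forward(x, train), train)
        return (path + res).astype(DTYPE)

    def backward(self, g: np.ndarray) -> np.ndarray:
        f1, f2, _ = self.splits
        g1 = g[:, :f1]
        g2 = g[:, f1:f1 + f2]
        g3 = g[:, f1 + f2:]
        d_o2 = self.sub3.backward(np.ascontiguousarray(g3))
        d_o1 = self.sub2.backward(np.ascontiguousarray(g2 + d_o2))
        dx = self.sub1.backward(np.ascontiguousarray(g1 + d_o1))
        if self.short_conv is None:
            dx = dx + g
        else:
            dx = dx + self.short_conv.backward(self.short_bn.backward(g))
        return dx.astype(DTYPE)
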