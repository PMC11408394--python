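"""3D convolutional building blocks on top of the autodiff :class:`Tensor`.

All layers operate on single volumes laid out channel-last, ``(X, Y, Z, C)``
(the networks train with batch size 1, so no batch axis is carried).
Parameters are float32; initialisation is variance-scaling fan-in.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Conv3d",
    "UpConv3d",
    "InstanceNorm",
    "ReLU",
    "LeakyReLU",
    "Dropout",
    "AvgPool2",
    "Softmax",
    "Sequential",
]


class Module:
    """Base class: parameter discovery by attribute walk, named hierarchically."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}" if prefix else name
            if isinstance(value, Tensor) and value.requires_grad:
                params[key] = value
            elif isinstance(value, Module):
                params.update(value.parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.parameters(prefix=f"{key}.{i}."))
        return params

    def __call__(self, x: Tensor, **kw) -> Tensor:
        return self.forward(x, **kw)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        for m in self.mods:
            x = m(x, training=training) if getattr(m, "_wants_training", False) else m(x)
        return x


class Conv3d(Module):
    """Same-padded 3D convolution with stride and dilation, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = kernel**3 * in_ch
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, kernel, in_ch, out_ch))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.kernel = kernel
        self.stride = stride
        self.dilation = dilation
        self.in_ch = in_ch
        self.out_ch = out_ch

    def forward(self, x: Tensor) -> Tensor:
        k, s, d = self.kernel, self.stride, self.dilation
        X, Y, Z, C = x.data.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        span = d * (k - 1) + 1
        pad = (span - 1) // 2
        Xo, Yo, Zo = -(-X // s), -(-Y // s), -(-Z // s)
        dtype = x.data.dtype
        xp = np.pad(x.data, ((pad, pad), (pad, pad), (pad, pad), (0, 0)))
        k3 = k**3
        offsets = [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]

        def slices(i, j, l):
            return (
                slice(i * d, i * d + s * (Xo - 1) + 1, s),
                slice(j * d, j * d + s * (Yo - 1) + 1, s),
                slice(l * d, l * d + s * (Zo - 1) + 1, s),
            )

        n = Xo * Yo * Zo
        # offset-major column buffer: contiguous writes, reused for dW
        cols = np.empty((k3, Xo, Yo, Zo, C), dtype=dtype)
        for idx, (i, j, l) in enumerate(offsets):
            cols[idx] = xp[slices(i, j, l)]
        cols_flat = cols.reshape(k3, n, C)
        w_flat = self.weight.data.reshape(k3, C, self.out_ch).astype(dtype, copy=False)
        out_flat = np.zeros((n, self.out_ch), dtype=dtype)
        for idx in range(k3):
            out_flat += cols_flat[idx] @ w_flat[idx]
        out_data = (out_flat + self.bias.data.astype(dtype, copy=False)).reshape(
            Xo, Yo, Zo, self.out_ch
        )

        weight, bias = self.weight, self.bias

        def backward(g):
            g_flat = np.ascontiguousarray(g, dtype=dtype).reshape(n, self.out_ch)
            if weight.requires_grad:
                dw = np.empty((k3, C, self.out_ch), dtype=dtype)
                for idx in range(k3):
                    dw[idx] = cols_flat[idx].T @ g_flat
                weight._accumulate(dw.reshape(weight.data.shape))
            if bias.requires_grad:
                bias._accumulate(g_flat.sum(axis=0))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                wt = np.ascontiguousarray(w_flat.transpose(0, 2, 1))
                for idx, (i, j, l) in enumerate(offsets):
                    dxp[slices(i, j, l)] += (g_flat @ wt[idx]).reshape(Xo, Yo, Zo, C)
                if pad:
                    dxp = dxp[pad:-pad, pad:-pad, pad:-pad, :]
                x._accumulate(dxp)

        return Tensor._make(out_data, (x, weight, bias), backward)


class UpConv3d(Module):
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_ch), size=(in_ch, 8 * out_ch))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.in_ch = in_ch
        self.out_ch = out_ch

    def forward(self, x: Tensor) -> Tensor:
        X, Y, Z, C = x.data.shape
        oc = self.out_ch
        t = (x.data.reshape(-1, C) @ self.weight.data).reshape(X, Y, Z, 2, 2, 2, oc)
        out_data = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5, 6)).reshape(
            2 * X, 2 * Y, 2 * Z, oc
        ) + self.bias.data

        weight, bias = self.weight, self.bias

        def backward(g):
            gt = g.reshape(X, 2, Y, 2, Z, 2, oc).transpose(0, 2, 4, 1, 3, 5, 6)
            gt_flat = np.ascontiguousarray(gt).reshape(-1, 8 * oc)
            if weight.requires_grad:
                weight._accumulate(x.data.reshape(-1, C).T @ gt_flat)
            if bias.requires_grad:
                bias._accumulate(g.reshape(-1, oc).sum(axis=0))
            if x.requires_grad:
                x._accumulate((gt_flat @ weight.data.T).reshape(X, Y, Z, C))

        return Tensor._make(out_data, (x, weight, bias), backward)


class InstanceNorm(Module):
    """Per-channel normalisation over the spatial axes with learned affine."""

    def __init__(self, ch: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(ch, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 1, 2)
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        std = np.sqrt(var + self.eps)
        xhat = (x.data - mu) / std
        out_data = xhat * self.gamma.data + self.beta.data
        gamma, beta = self.gamma, self.beta

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gh = g * gamma.data
                mean_gh = gh.mean(axis=axes, keepdims=True)
                mean_gh_xhat = (gh * xhat).mean(axis=axes, keepdims=True)
                x._accumulate((gh - mean_gh - xhat * mean_gh_xhat) / std)

        return Tensor._make(out_data, (x, gamma, beta), backward)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        mask = x.data > 0

        def backward(g):
            if x.requires_grad:
                x._accumulate(g * mask)

        return Tensor._make(x.data * mask, (x,), backward)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        factor = np.where(x.data > 0, 1.0, self.slope).astype(x.data.dtype)

        def backward(g):
            if x.requires_grad:
                x._accumulate(g * factor)

        return Tensor._make(x.data * factor, (x,), backward)


class Dropout(Module):
    """Inverted dropout; identity outside training."""

    _wants_training = True

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor, training: bool = False) -> Tensor:
        if not training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep

        def backward(g):
            if x.requires_grad:
                x._accumulate(g * mask)

        return Tensor._make(x.data * mask, (x,), backward)


class AvgPool2(Module):
    """Factor-2 average pooling along each spatial axis."""

    def forward(self, x: Tensor) -> Tensor:
        X, Y, Z, C = x.data.shape
        out_data = x.data.reshape(X // 2, 2, Y // 2, 2, Z // 2, 2, C).mean(axis=(1, 3, 5))

        def backward(g):
            if x.requires_grad:
                gx = np.repeat(np.repeat(np.repeat(g, 2, 0), 2, 1), 2, 2) / 8.0
                x._accumulate(gx)

        return Tensor._make(out_data, (x,), backward)


class Softmax(Module):
    """Softmax over the channel (last) axis."""

    def forward(self, x: Tensor) -> Tensor:
        z = x.data - x.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            if x.requires_grad:
                g = g.astype(y.dtype, copy=False)  # loss math may be float64
                dot = (g * y).sum(axis=-1, keepdims=True)
                x._accumulate(y * (g - dot))

        return Tensor._make(y, (x,), backward)
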