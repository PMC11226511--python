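"""Neural-network modules on top of the autograd core.

He fan-in initialisation for convolution weights, zero biases, unit/zero
group-norm affine; every module draws from the generator it is given so
construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, _attach
from . import conv as C

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "GroupNorm",
    "LeakyReLU",
    "Sequential",
]


class Module:
    """Base class tracking parameters and submodules by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = float(np.sqrt(2.0 / fan_in))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=0, dil=1, groups=1, *, rng):
        super().__init__()
        if groups not in (1, cin) or (groups == cin and cout != cin and groups != 1):
            raise ValueError("only dense (groups=1) or depthwise convs are supported")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad, self.dil, self.groups = stride, pad, dil, groups
        fan_in = (cin // groups) * k**3
        self.weight = Parameter(_he_normal(rng, (cout, cin // groups, k, k, k), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        w, b = self.weight, self.bias
        y = C.conv3d_forward(
            x.data, w.data, b.data, self.stride, self.pad, self.dil, self.groups
        )
        out = Tensor(y, _prev=(x, w, b))
        need_dx = x.requires_grad or x._prev

        def back(g):
            dx, dw, db = C.conv3d_backward(
                x.data, w.data, g, self.stride, self.pad, self.dil, self.groups,
                need_dx=bool(need_dx),
            )
            w.accumulate(dw)
            b.accumulate(db)
            if dx is not None:
                x.accumulate(dx)

        _attach(out, back)
        return out


class ConvTranspose3d(Module):
    """Stride-s transposed convolution; kernel 4, stride 2, pad 1 doubles dims."""

    def __init__(self, cin, cout, k=4, stride=2, pad=1, *, rng):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.weight = Parameter(_he_normal(rng, (cin, cout, k, k, k), cin * k**3))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        w, b = self.weight, self.bias
        y = C.conv_transpose3d_forward(x.data, w.data, b.data, self.stride, self.pad)
        out = Tensor(y, _prev=(x, w, b))
        need_dx = x.requires_grad or x._prev

        def back(g):
            dx, dw, db = C.conv_transpose3d_backward(
                x.data, w.data, g, self.stride, self.pad, need_dx=bool(need_dx)
            )
            w.accumulate(dw)
            b.accumulate(db)
            if dx is not None:
                x.accumulate(dx)

        _attach(out, back)
        return out


class GroupNorm(Module):
    """Group normalisation over (channels/groups, spatial) per sample.

    Batch-size independent, which matters at batch size 1.  Per-channel
    affine scale/shift; ``affine=False`` drops them.
    """

    def __init__(self, channels: int, groups: int | None = None, eps: float = 1e-5,
                 affine: bool = True):
        super().__init__()
        self.channels = channels
        self.groups = min(8, channels) if groups is None else groups
        if channels % self.groups != 0:
            raise ValueError(f"groups={self.groups} must divide channels={channels}")
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones(channels, dtype=np.float32))
            self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        N, Ch = x.shape[:2]
        if Ch != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {Ch}")
        G = self.groups
        xg = x.data.reshape(N, G, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * invstd).reshape(x.shape)
        cshape = (1, Ch) + (1,) * (x.data.ndim - 2)
        if self.affine:
            y = xhat * self.gamma.data.reshape(cshape) + self.beta.data.reshape(cshape)
            prev = (x, self.gamma, self.beta)
        else:
            y = xhat
            prev = (x,)
        out = Tensor(y.astype(np.float32), _prev=prev)

        def back(g):
            if self.affine:
                axes = (0,) + tuple(range(2, g.ndim))
                self.gamma.accumulate((g * xhat).sum(axis=axes))
                self.beta.accumulate(g.sum(axis=axes))
                dxhat = g * self.gamma.data.reshape(cshape)
            else:
                dxhat = g
            dxh = dxhat.reshape(N, G, -1)
            xh = xhat.reshape(N, G, -1)
            m1 = dxh.mean(axis=2, keepdims=True)
            m2 = (dxh * xh).mean(axis=2, keepdims=True)
            dx = (invstd * (dxh - m1 - xh * m2)).reshape(x.shape)
            x.accumulate(dx.astype(np.float32))

        _attach(out, back)
        return out


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
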