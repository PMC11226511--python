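"""3D large-kernel attention.

The module normalises and activates its input, pushes it through the
decomposed large-kernel convolution chain (depthwise, depthwise-dilated,
pointwise), squashes the result through a sigmoid to obtain a spatial/
channel attention map in (0, 1), and gates the normalised input
multiplicatively with a residual add:

    z   = lReLU(GN(x))
    A   = sigmoid(pointwise(DWD(DW(z))))
    out = A * z + z

so the gate amplifies features by a factor in (1, 2) and can never erase
them.  A dense (undecomposed) large-kernel variant is provided for
parameter-accounting comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom as _ndzoom

from . import nn
from .complexity import (
    DecompositionSpec,
    count_decomposed_params,
    count_original_params,
    decompose_kernel,
)

__all__ = [
    "LKAttention3d",
    "OriginalLKAttention3d",
    "AttentionOutput",
    "build_lk_attention",
    "attention_forward",
    "receptive_field",
    "upsample_attention_map",
]

LEAKY_SLOPE = 0.01


@dataclass
class AttentionOutput:
    output: nn.Tensor
    attention_map: nn.Tensor


class LKAttention3d(nn.Module):
    """Decomposed large-kernel attention over a channel-preserving feature map.

    Parameters
    ----------
    channels:
        Channel count C of the gated feature map.
    K, d:
        Equal large-kernel side and dilation of the decomposition.
    order:
        ``"dw_first"`` applies DW then DWD (default); ``"dwd_first"`` swaps
        them.  Both orders have identical parameter counts and receptive
        fields.
    residual:
        ``"normed"`` adds the normalised-activated input (default);
        ``"raw"`` adds the raw input instead.
    """

    def __init__(self, channels: int, K: int, d: int, *, rng,
                 order: str = "dw_first", residual: str = "normed",
                 gn_affine: bool = True):
        super().__init__()
        if order not in ("dw_first", "dwd_first"):
            raise ValueError(f"unknown conv order {order!r}")
        if residual not in ("normed", "raw"):
            raise ValueError(f"unknown residual mode {residual!r}")
        self.channels = channels
        self.spec: DecompositionSpec = decompose_kernel(K, d)
        self.order = order
        self.residual = residual
        self.norm = nn.GroupNorm(channels, affine=gn_affine)
        s = self.spec
        self.dw = nn.Conv3d(channels, channels, s.k_dw, pad=s.pad_dw[0],
                            groups=channels, rng=rng)
        self.dwd = nn.Conv3d(channels, channels, s.k_dwd, pad=s.pad_dwd[0],
                             dil=s.d, groups=channels, rng=rng)
        self.pointwise = nn.Conv3d(channels, channels, 1, rng=rng)
        expected = count_decomposed_params(channels, K, d)
        got = self.conv_parameter_count()
        if got != expected:
            raise AssertionError(
                f"attention conv parameter count {got} != closed form {expected}"
            )

    def conv_parameter_count(self) -> int:
        """Trainable weights+biases of the three convolutions (GN excluded)."""
        return sum(
            int(m.weight.data.size + m.bias.data.size)
            for m in (self.dw, self.dwd, self.pointwise)
        )

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"channel mismatch: module has {self.channels}, input has {x.shape[1]}"
            )
        z = self.norm(x).leaky_relu(LEAKY_SLOPE)
        if self.order == "dw_first":
            h = self.dwd(self.dw(z))
        else:
            h = self.dw(self.dwd(z))
        a = self.pointwise(h).sigmoid()
        base = z if self.residual == "normed" else x
        out = a * z + base
        return out, a


class OriginalLKAttention3d(nn.Module):
    """Undecomposed variant: one dense C->C convolution with a K^3 kernel.

    Only size-preserving odd kernels are supported for the forward pass;
    even kernels (e.g. K=6) can still be constructed for parameter
    accounting, mirroring the decomposed module's comparison role.
    """

    def __init__(self, channels: int, K: int, *, rng, residual: str = "normed"):
        super().__init__()
        self.channels = channels
        self.K = K
        self.residual = residual
        self.norm = nn.GroupNorm(channels)
        self.conv = nn.Conv3d(channels, channels, K, pad=(K - 1) // 2, rng=rng)
        expected = count_original_params(channels, K)
        got = self.conv_parameter_count()
        if got != expected:
            raise AssertionError(
                f"original LK conv parameter count {got} != closed form {expected}"
            )

    def conv_parameter_count(self) -> int:
        return int(self.conv.weight.data.size + self.conv.bias.data.size)

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        if self.K % 2 == 0:
            raise ValueError(
                f"even kernel K={self.K} cannot preserve spatial size; "
                "this variant exists for parameter accounting"
            )
        z = self.norm(x).leaky_relu(LEAKY_SLOPE)
        a = self.conv(z).sigmoid()
        base = z if self.residual == "normed" else x
        return a * z + base, a


def build_lk_attention(channels: int, K: int, d: int, seed: int = 0,
                       **kwargs) -> LKAttention3d:
    """Deterministically construct an attention module under `seed`."""
    rng = np.random.default_rng(seed)
    return LKAttention3d(channels, K, d, rng=rng, **kwargs)


def attention_forward(module: LKAttention3d, x) -> AttentionOutput:
    """Apply the module to an array or Tensor; returns output and map."""
    t = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=np.float32))
    out, a = module(t)
    return AttentionOutput(output=out, attention_map=a)


def receptive_field(spec: DecompositionSpec) -> int:
    """Side of the cubic input footprint of the DW∘DWD chain."""
    return spec.receptive_field


def upsample_attention_map(a: np.ndarray, target_shape) -> np.ndarray:
    """Nearest-neighbour upsample a (C, D, H, W) map onto a full-res grid."""
    a = np.asarray(a)
    if a.ndim == 5:  # drop batch
        a = a[0]
    factors = [t / s for t, s in zip(target_shape, a.shape[1:])]
    return _ndzoom(a, [1.0] + factors, order=0)
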