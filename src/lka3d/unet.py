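"""Six-scale 3D encoder-decoder with deep supervision and configurable
large-kernel attention placement.

The encoder doubles channels from ``base_width`` (capped at ``max_width``)
over ``n_scales`` scales, halving resolution with stride-2 convolutions so
the deepest map is ``1/2**(n_scales-1)`` of the input.  The decoder
mirrors it with 4^3 stride-2 transposed convolutions; an attention module
can be placed directly after any transposed convolution, before the skip
concatenation, where the channel counts are 32/64/128/256/512 from finest
to coarsest decoder scale.  Segmentation heads (1x1x1 convolutions) sit at
every scale except the two lowest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import nn
from .attention import LKAttention3d, OriginalLKAttention3d, LEAKY_SLOPE
from .complexity import count_decomposed_params, count_original_params

__all__ = [
    "Placement",
    "NetworkConfig",
    "LKAUNet3d",
    "build_network",
    "network_forward",
    "count_network_params",
    "parameter_breakdown",
    "reconcile_base_total",
    "base_config",
    "mid_config",
    "full_config",
    "FULL_PLACEMENTS",
]


@dataclass(frozen=True)
class Placement:
    """An attention module at decoder scale `scale` (0 = finest)."""

    scale: int
    K: int
    d: int
    kind: str = "decomposed"  # or "original"


# Decoder-scale placements of the fully-equipped network, coarsest first:
# (scale index, equal LK kernel, dilation) at channels 512/256/128/64/32.
FULL_PLACEMENTS: tuple[Placement, ...] = (
    Placement(4, 6, 2),
    Placement(3, 6, 2),
    Placement(2, 10, 2),
    Placement(1, 15, 3),
    Placement(0, 21, 3),
)


@dataclass
class NetworkConfig:
    in_channels: int = 1
    out_channels: int = 7
    base_width: int = 32
    max_width: int = 512
    n_scales: int = 6
    attention_placements: list[Placement] = field(default_factory=list)
    head_activation: str = "softmax"  # or "sigmoid"
    deep_supervision: bool = True
    input_shape: tuple[int, int, int] = (160, 192, 128)
    attention_order: str = "dw_first"
    attention_residual: str = "normed"
    attention_gn_affine: bool = True

    def __post_init__(self):
        self.attention_placements = [
            p if isinstance(p, Placement) else Placement(*p)
            for p in self.attention_placements
        ]
        if self.head_activation not in ("softmax", "sigmoid"):
            raise ValueError(f"unknown head activation {self.head_activation!r}")
        div = 2 ** (self.n_scales - 1)
        if any(s % div != 0 for s in self.input_shape):
            raise ValueError(
                f"input shape {self.input_shape} must be divisible by {div} "
                f"for {self.n_scales} scales"
            )
        for p in self.attention_placements:
            if not (0 <= p.scale <= self.n_scales - 2):
                raise ValueError(
                    f"placement scale {p.scale} outside decoder range "
                    f"0..{self.n_scales - 2}"
                )

    @property
    def widths(self) -> list[int]:
        return [min(self.base_width * 2**s, self.max_width) for s in range(self.n_scales)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["attention_placements"] = [
            [p.scale, p.K, p.d, p.kind] for p in self.attention_placements
        ]
        d["input_shape"] = list(self.input_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["attention_placements"] = [Placement(*p) for p in d.get("attention_placements", [])]
        d["input_shape"] = tuple(d.get("input_shape", (160, 192, 128)))
        return cls(**d)


class _ConvBlock(nn.Module):
    """Two 3^3 convolutions, each followed by GN and leaky ReLU."""

    def __init__(self, cin, cout, *, rng):
        super().__init__()
        self.c1 = nn.Conv3d(cin, cout, 3, pad=1, rng=rng)
        self.n1 = nn.GroupNorm(cout)
        self.c2 = nn.Conv3d(cout, cout, 3, pad=1, rng=rng)
        self.n2 = nn.GroupNorm(cout)

    def forward(self, x):
        x = self.n1(self.c1(x)).leaky_relu(LEAKY_SLOPE)
        return self.n2(self.c2(x)).leaky_relu(LEAKY_SLOPE)


class _Down(nn.Module):
    """Stride-2 3^3 transition convolution with GN + leaky ReLU."""

    def __init__(self, cin, cout, *, rng):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, 3, stride=2, pad=1, rng=rng)
        self.norm = nn.GroupNorm(cout)

    def forward(self, x):
        return self.norm(self.conv(x)).leaky_relu(LEAKY_SLOPE)


class LKAUNet3d(nn.Module):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.widths
        S = config.n_scales

        for s in range(S):
            cin = config.in_channels if s == 0 else w[s]
            setattr(self, f"enc{s}", _ConvBlock(cin, w[s], rng=rng))
            if s < S - 1:
                setattr(self, f"down{s}", _Down(w[s], w[s + 1], rng=rng))

        placements = {p.scale: p for p in config.attention_placements}
        for s in reversed(range(S - 1)):  # decoder scales, coarsest first
            src = w[s + 1]
            setattr(self, f"up{s}", nn.ConvTranspose3d(src, w[s], 4, 2, 1, rng=rng))
            if s in placements:
                p = placements[s]
                if p.kind == "decomposed":
                    att = LKAttention3d(
                        w[s], p.K, p.d, rng=rng,
                        order=config.attention_order,
                        residual=config.attention_residual,
                        gn_affine=config.attention_gn_affine,
                    )
                else:
                    att = OriginalLKAttention3d(
                        w[s], p.K, rng=rng, residual=config.attention_residual
                    )
                setattr(self, f"att{s}", att)
            setattr(self, f"dec{s}", _ConvBlock(2 * w[s], w[s], rng=rng))

        self.head_scales = [s for s in range(S - 1) if s <= S - 3] or [0]
        for s in self.head_scales:
            setattr(self, f"head{s}", nn.Conv3d(w[s], config.out_channels, 1, rng=rng))

    # -- forward ----------------------------------------------------------

    def forward(self, x: nn.Tensor):
        cfg = self.config
        if x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected {cfg.in_channels} input channels, got {x.shape[1]}"
            )
        div = 2 ** (cfg.n_scales - 1)
        if any(s % div != 0 for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {div}"
            )
        S = cfg.n_scales
        skips = []
        h = x
        for s in range(S):
            h = getattr(self, f"enc{s}")(h)
            skips.append(h)
            if s < S - 1:
                h = getattr(self, f"down{s}")(h)

        attention_maps: dict[int, nn.Tensor] = {}
        logits: dict[int, nn.Tensor] = {}
        for s in reversed(range(S - 1)):
            h = getattr(self, f"up{s}")(h)
            att = getattr(self, f"att{s}", None)
            if att is not None:
                h, a = att(h)
                attention_maps[s] = a
            h = getattr(self, f"dec{s}")(nn.concat([h, skips[s]], axis=1))
            if s in self.head_scales:
                logits[s] = getattr(self, f"head{s}")(h)

        main = logits[0]
        aux = [logits[s] for s in self.head_scales if s != 0] if cfg.deep_supervision else []
        return main, aux, attention_maps


def build_network(config: NetworkConfig, seed: int = 0) -> LKAUNet3d:
    return LKAUNet3d(config, seed=seed)


def network_forward(net: LKAUNet3d, volume) -> tuple[nn.Tensor, list[nn.Tensor], dict]:
    t = volume if isinstance(volume, nn.Tensor) else nn.Tensor(
        np.asarray(volume, dtype=np.float32)
    )
    return net(t)


def count_network_params(net: LKAUNet3d) -> int:
    return net.n_parameters()


def parameter_breakdown(net: LKAUNet3d) -> dict[str, int]:
    """Per-component trainable-parameter counts (attention split conv/GN)."""
    out: dict[str, int] = {}
    for name, mod in net._modules.items():
        if isinstance(mod, (LKAttention3d, OriginalLKAttention3d)):
            out[name + ".convs"] = mod.conv_parameter_count()
            out[name + ".gn"] = mod.n_parameters() - mod.conv_parameter_count()
        else:
            out[name] = mod.n_parameters()
    return out


def attention_conv_params(config: NetworkConfig) -> int:
    """Closed-form sum of attention conv parameters over the placements."""
    w = config.widths
    total = 0
    for p in config.attention_placements:
        if p.kind == "decomposed":
            total += count_decomposed_params(w[p.scale], p.K, p.d)
        else:
            total += count_original_params(w[p.scale], p.K)
    return total


def reconcile_base_total(net: LKAUNet3d, reference_total: int | None = None) -> dict:
    """Reconcile the network's exact count against its component breakdown
    (and optionally an external reference total)."""
    breakdown = parameter_breakdown(net)
    total = count_network_params(net)
    rec = {
        "total": total,
        "breakdown_sum": sum(breakdown.values()),
        "breakdown": breakdown,
    }
    if reference_total is not None:
        rec["reference_total"] = reference_total
        rec["gap"] = total - reference_total
    return rec


# -- canonical variants ---------------------------------------------------


def base_config(in_channels=1, out_channels=7,
                input_shape=(160, 192, 128), **kw) -> NetworkConfig:
    return NetworkConfig(in_channels=in_channels, out_channels=out_channels,
                         input_shape=tuple(input_shape), **kw)


def mid_config(in_channels=1, out_channels=7,
               input_shape=(160, 192, 128), **kw) -> NetworkConfig:
    """One equal-21 attention module at the middle decoder scale (C=128)."""
    return NetworkConfig(
        in_channels=in_channels, out_channels=out_channels,
        input_shape=tuple(input_shape),
        attention_placements=[Placement(2, 21, 3)], **kw,
    )


def full_config(in_channels=1, out_channels=7,
                input_shape=(160, 192, 128), **kw) -> NetworkConfig:
    """Attention at every decoder scale with the canonical kernel schedule."""
    return NetworkConfig(
        in_channels=in_channels, out_channels=out_channels,
        input_shape=tuple(input_shape),
        attention_placements=list(FULL_PLACEMENTS), **kw,
    )
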