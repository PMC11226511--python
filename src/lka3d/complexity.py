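"""Closed-form complexity calculus for decomposed large-kernel 3D convolutions.

A cubic K x K x K convolution over C channels can be decomposed into a
(2d-1)^3 depthwise convolution, a (K/d)^3 depthwise convolution with
dilation d, and a 1x1x1 pointwise convolution.  This module provides the
geometry of that decomposition and exact integer parameter / FLOP counts
for the original and decomposed forms, the continuous dilation that
minimises the decomposed count, and the kernel-coverage statistic used to
reason about where in a network a large-kernel module pays off.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DecompositionSpec",
    "ComplexityRow",
    "decompose_kernel",
    "count_original_params",
    "count_decomposed_params",
    "count_flops",
    "optimal_dilation",
    "best_integer_dilation",
    "kernel_coverage",
    "complexity_table",
    "format_count",
    "format_table",
]


@dataclass(frozen=True)
class DecompositionSpec:
    """Kernel/dilation geometry of a decomposed large-kernel convolution.

    ``K`` is the equal large-kernel side being emulated, ``d`` the dilation.
    The depthwise kernel side is ``2d - 1``, the depthwise-dilated kernel
    side is ``K / d``; the paddings keep every convolution in the chain
    "same"-sized at stride 1.
    """

    K: int
    d: int
    k_dw: int
    k_dwd: int
    pad_dw: tuple[int, int, int]
    pad_dwd: tuple[int, int, int]

    @property
    def receptive_field(self) -> int:
        """Side of the cubic input region seen by one output voxel of DW∘DWD."""
        return self.k_dw + self.d * (self.k_dwd - 1)


@dataclass(frozen=True)
class ComplexityRow:
    C: int
    n_prm_original: int
    n_prm_decomposed: int
    ratio: float
    flops_original: int
    flops_decomposed: int


def decompose_kernel(K: int, d: int) -> DecompositionSpec:
    """Decompose a K^3 large kernel at dilation d.

    Returns the depthwise kernel side ``2d-1``, the dilated kernel side
    ``K/d``, and the zero paddings that keep each convolution
    size-preserving at stride 1.  Rejects (K, d) pairs where d does not
    divide K, or where the dilated kernel cannot be padded symmetrically.
    """
    if K < 1 or d < 1:
        raise ValueError(f"K and d must be positive, got K={K}, d={d}")
    if K % d != 0:
        raise ValueError(
            f"dilation d={d} must divide the kernel size K={K} "
            "(the decomposition requires K/d to be an integer kernel side)"
        )
    k_dw = 2 * d - 1
    k_dwd = K // d
    pad_dw = d - 1  # ((2d-1) - 1) / 2
    span = d * (k_dwd - 1)  # dilated extent minus one
    if span % 2 != 0:
        raise ValueError(
            f"(K={K}, d={d}) gives a dilated kernel of even effective extent "
            f"{span + 1}; a symmetric size-preserving padding does not exist"
        )
    pad_dwd = span // 2
    return DecompositionSpec(
        K=K,
        d=d,
        k_dw=k_dw,
        k_dwd=k_dwd,
        pad_dw=(pad_dw,) * 3,
        pad_dwd=(pad_dwd,) * 3,
    )


def count_original_params(C: int, K: int) -> int:
    """Parameters of a dense C->C convolution with a K^3 kernel (with bias)."""
    if C < 1 or K < 1:
        raise ValueError(f"C and K must be positive, got C={C}, K={K}")
    return C * (C * K**3 + 1)


def count_decomposed_params(C: int, K: int, d: int) -> int:
    """Parameters of the decomposed chain: C*((2d-1)^3 + (K/d)^3 + C + 3).

    The ``+ C`` term is the pointwise C x C mixing weights per output
    channel; the ``+ 3`` is one bias on each of the three convolutions.
    """
    if C < 1:
        raise ValueError(f"C must be positive, got C={C}")
    spec = decompose_kernel(K, d)
    return C * (spec.k_dw**3 + spec.k_dwd**3 + C + 3)


def count_flops(params: int, dims: Sequence[int]) -> int:
    """Multiply-accumulate count: the parameter count times the voxel count."""
    if params < 0:
        raise ValueError("params must be non-negative")
    dims = tuple(int(x) for x in dims)
    if len(dims) != 3 or any(x < 1 for x in dims):
        raise ValueError(f"dims must be a positive triple, got {dims}")
    return params * dims[0] * dims[1] * dims[2]


def _stationarity(d: float, K: int) -> float:
    # d/dd of (2d-1)^3 + (K/d)^3, scaled by 1: 6(2d-1)^2 - 3K^3/d^4
    # expanded: 24 d^2 - 24 d - 3 K^3 / d^4 + 6
    return 24.0 * d * d - 24.0 * d - 3.0 * K**3 / d**4 + 6.0


def optimal_dilation(K: int, tol: float = 1e-9) -> float:
    """Continuous dilation minimising the d-dependent part of the decomposed count.

    Solves 24 d^2 - 24 d - 3 K^3 / d^4 + 6 = 0 on the bracket [1, K] by a
    bracketing root finder.  The returned root is the unconstrained
    minimiser of d -> (2d-1)^3 + (K/d)^3 over positive reals.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2 for a non-degenerate optimum, got K={K}")
    lo, hi = 1.0, float(K)
    flo, fhi = _stationarity(lo, K), _stationarity(hi, K)
    if flo == 0.0:
        return lo
    if flo * fhi > 0:
        raise ValueError(f"no sign change on bracket [1, {K}] for K={K}")
    return float(brentq(_stationarity, lo, hi, args=(K,), xtol=tol))


def best_integer_dilation(C: int, K: int) -> int:
    """Best integer dilation: evaluate the exact count at the divisors of K
    bracketing the continuous optimum and return the cheaper one."""
    d_star = optimal_dilation(K)
    divisors = [d for d in range(1, K + 1) if K % d == 0]
    lower = max((d for d in divisors if d <= d_star), default=divisors[0])
    upper = min((d for d in divisors if d >= d_star), default=divisors[-1])
    candidates = sorted({lower, upper})

    def cost(d: int) -> int:
        try:
            return count_decomposed_params(C, K, d)
        except ValueError:
            return count_original_params(C, K) + 1  # unusable geometry

    return min(candidates, key=cost)


def kernel_coverage(kernel: Sequence[int], scale: Sequence[int]) -> float:
    """Ratio of kernel voxel volume to feature-space voxel volume."""
    kernel = tuple(int(x) for x in kernel)
    scale = tuple(int(x) for x in scale)
    if len(kernel) != 3 or len(scale) != 3:
        raise ValueError("kernel and scale must be triples")
    if any(x < 1 for x in kernel) or any(x < 1 for x in scale):
        raise ValueError("kernel and scale entries must be positive")
    return float(np.prod(kernel) / np.prod(scale))


def complexity_table(
    channel_list: Sequence[int], K: int, d: int, dims: Sequence[int] = (1, 1, 1)
) -> list[ComplexityRow]:
    """One row per channel count comparing original vs decomposed costs."""
    rows = []
    for C in channel_list:
        n_o = count_original_params(C, K)
        n_d = count_decomposed_params(C, K, d)
        rows.append(
            ComplexityRow(
                C=C,
                n_prm_original=n_o,
                n_prm_decomposed=n_d,
                ratio=n_d / n_o,
                flops_original=count_flops(n_o, dims),
                flops_decomposed=count_flops(n_d, dims),
            )
        )
    return rows


def format_count(n: int) -> str:
    """Render an integer count with two-decimal half-up rounding in k or M."""
    if n >= 10**6:
        q = (Decimal(n) / Decimal(10**6)).quantize(Decimal("0.01"), ROUND_HALF_UP)
        return f"{q} M"
    q = (Decimal(n) / Decimal(10**3)).quantize(Decimal("0.01"), ROUND_HALF_UP)
    return f"{q} k"


def format_ratio(r: float) -> str:
    q = (Decimal(repr(r * 100))).quantize(Decimal("0.01"), ROUND_HALF_UP)
    return f"{q}%"


def format_table(rows: Sequence[ComplexityRow]) -> str:
    header = f"{'C':>6} {'N_PRM,O':>12} {'N_PRM,D':>12} {'D/O':>8}"
    lines = [header]
    for r in rows:
        lines.append(
            f"{r.C:>6} {format_count(r.n_prm_original):>12} "
            f"{format_count(r.n_prm_decomposed):>12} {format_ratio(r.ratio):>8}"
        )
    return "\n".join(lines)
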