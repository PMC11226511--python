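"""Large-kernel attention module: oracle equivalence, gating bounds,
depthwise isolation, receptive field, parameter accounting."""

import numpy as np
import pytest

from lka3d import nn
from lka3d.attention import (
    LKAttention3d,
    OriginalLKAttention3d,
    attention_forward,
    build_lk_attention,
    receptive_field,
    upsample_attention_map,
)
from lka3d.complexity import count_decomposed_params, decompose_kernel

TABLE_CONFIGS = [  # (channels, K, d) of the fully-equipped network
    (512, 6, 2),
    (256, 6, 2),
    (128, 10, 2),
    (64, 15, 3),
    (32, 21, 3),
]


def naive_depthwise(x, w, b, dil):
    """Nested-loop depthwise 'same' convolution, float64."""
    C = x.shape[0]
    k = w.shape[1]
    pad = dil * (k - 1) // 2
    xp = np.pad(x.astype(np.float64), ((0, 0),) + ((pad, pad),) * 3)
    y = np.zeros_like(x, dtype=np.float64)
    for c in range(C):
        for z in range(x.shape[1]):
            for yy in range(x.shape[2]):
                for xx in range(x.shape[3]):
                    acc = 0.0
                    for a in range(k):
                        for bb in range(k):
                            for cc in range(k):
                                acc += (
                                    xp[c, z + a * dil, yy + bb * dil, xx + cc * dil]
                                    * w[c, a, bb, cc]
                                )
                    y[c, z, yy, xx] = acc + b[c]
    return y


def naive_attention(module, x):
    """Re-evaluate the whole attention definition with independent code."""
    C = module.channels
    G = module.norm.groups
    xg = x.reshape(G, -1).astype(np.float64)
    mu = xg.mean(axis=1, keepdims=True)
    var = xg.var(axis=1, keepdims=True)
    z = ((xg - mu) / np.sqrt(var + module.norm.eps)).reshape(x.shape)
    if module.norm.affine:
        z = z * module.norm.gamma.data.reshape(-1, 1, 1, 1) \
            + module.norm.beta.data.reshape(-1, 1, 1, 1)
    z = np.where(z > 0, z, 0.01 * z)
    h = naive_depthwise(z, module.dw.weight.data[:, 0], module.dw.bias.data, 1)
    h = naive_depthwise(h, module.dwd.weight.data[:, 0], module.dwd.bias.data,
                        module.spec.d)
    pw = module.pointwise.weight.data.reshape(C, C)
    a = np.einsum("oc,czyx->ozyx", pw, h) + module.pointwise.bias.data.reshape(-1, 1, 1, 1)
    a = 1.0 / (1.0 + np.exp(-a))
    return a * z + z, a


def test_forward_matches_direct_convolution_oracle():
    module = build_lk_attention(2, 6, 2, seed=3)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1, 2, 6, 6, 6)).astype(np.float32)
    res = attention_forward(module, x)
    want_out, want_a = naive_attention(module, x[0])
    np.testing.assert_allclose(res.attention_map.data[0], want_a, atol=1e-5)
    np.testing.assert_allclose(res.output.data[0], want_out, atol=1e-5)


def test_impulse_response_matches_oracle():
    module = build_lk_attention(2, 6, 2, seed=5)
    x = np.zeros((1, 2, 7, 7, 7), dtype=np.float32)
    x[0, 0, 3, 3, 3] = 1.0
    res = attention_forward(module, x)
    want_out, _ = naive_attention(module, x[0])
    np.testing.assert_allclose(res.output.data[0], want_out, atol=1e-5)


def test_zero_weights_give_half_attention_everywhere():
    module = build_lk_attention(3, 6, 2, seed=0)
    for conv in (module.dw, module.dwd, module.pointwise):
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 0.0
    x = np.random.default_rng(1).normal(size=(1, 3, 5, 5, 5)).astype(np.float32)
    res = attention_forward(module, x)
    np.testing.assert_allclose(res.attention_map.data, 0.5, atol=1e-7)
    # output is 1.5x the normalised-activated input
    z = module.norm(nn.Tensor(x)).leaky_relu(0.01).data
    np.testing.assert_allclose(res.output.data, 1.5 * z, atol=1e-6)


@pytest.mark.parametrize("channels,K,d", [(4, 6, 2), (2, 10, 2), (3, 21, 3)])
def test_shape_preservation_and_gating_bounds(channels, K, d):
    module = build_lk_attention(channels, K, d, seed=1)
    x = np.random.default_rng(2).normal(size=(2, channels, 6, 7, 5)).astype(np.float32)
    res = attention_forward(module, x)
    assert res.output.shape == x.shape
    a = res.attention_map.data
    assert np.all(a > 0.0) and np.all(a < 1.0)
    z = module.norm(nn.Tensor(x)).leaky_relu(0.01).data
    nz = np.abs(z) > 1e-4
    ratio = res.output.data[nz] / z[nz]
    assert np.all(ratio > 1.0) and np.all(ratio < 2.0)


def test_deepest_scale_module_at_true_width():
    """C=512 module on the 10x12x8 grid (the network's deepest scale)."""
    module = build_lk_attention(512, 6, 2, seed=0)
    x = np.random.default_rng(3).normal(size=(1, 512, 10, 12, 8)).astype(np.float32)
    res = attention_forward(module, x)
    assert res.output.shape == (1, 512, 10, 12, 8)
    assert module.conv_parameter_count() == 291_328


def test_depthwise_isolation_before_pointwise():
    """Zeroing input channel j leaves channel i != j of the depthwise chain
    untouched: only the 1x1x1 convolution mixes channels."""
    module = build_lk_attention(3, 6, 2, seed=7)
    rng = np.random.default_rng(4)
    x = rng.normal(size=(1, 3, 6, 6, 6)).astype(np.float32)

    def chain(x_):
        h = module.dw(nn.Tensor(x_))
        return module.dwd(h).data

    base = chain(x)
    x2 = x.copy()
    x2[0, 1] = 0.0
    mod = chain(x2)
    np.testing.assert_array_equal(base[0, 0], mod[0, 0])
    np.testing.assert_array_equal(base[0, 2], mod[0, 2])
    assert not np.allclose(base[0, 1], mod[0, 1])


@pytest.mark.parametrize("K,d,expected", [(21, 3, 23), (6, 2, 7), (1, 1, 1),
                                          (10, 2, 11), (15, 3, 17)])
def test_receptive_field_formula(K, d, expected):
    assert receptive_field(decompose_kernel(K, d)) == expected


@pytest.mark.parametrize("K,d", [(6, 2), (10, 2), (9, 3)])
def test_receptive_field_matches_gradient_footprint(K, d):
    """Backpropagate from one centre voxel of the DW∘DWD chain and measure
    the cube of input voxels with nonzero gradient."""
    spec = decompose_kernel(K, d)
    rf = receptive_field(spec)
    size = rf + 4
    module = build_lk_attention(1, K, d, seed=9)
    x = nn.Tensor(np.random.default_rng(5).normal(size=(1, 1, size, size, size)),
                  requires_grad=True)
    y = module.dwd(module.dw(x))
    g = np.zeros(y.shape, dtype=np.float32)
    mid = size // 2
    g[0, 0, mid, mid, mid] = 1.0
    y.backward(g)
    nz = np.nonzero(x.grad[0, 0])
    extent = [int(n.max() - n.min() + 1) for n in nz]
    assert extent == [rf, rf, rf]


@pytest.mark.parametrize("channels,K,d", TABLE_CONFIGS)
def test_construction_count_matches_closed_form(channels, K, d):
    module = build_lk_attention(channels, K, d, seed=0)
    assert module.conv_parameter_count() == count_decomposed_params(channels, K, d)


def test_trivial_module_has_six_conv_parameters():
    module = build_lk_attention(1, 1, 1, seed=0)
    assert module.conv_parameter_count() == 6  # 3 weights + 3 biases


def test_channel_mismatch_rejected():
    module = build_lk_attention(4, 6, 2, seed=0)
    with pytest.raises(ValueError, match="4"):
        attention_forward(module, np.zeros((1, 3, 4, 4, 4), dtype=np.float32))


def test_conv_order_switch_preserves_count_and_shape():
    rng = np.random.default_rng(0)
    a = LKAttention3d(2, 6, 2, rng=np.random.default_rng(1), order="dw_first")
    b = LKAttention3d(2, 6, 2, rng=np.random.default_rng(1), order="dwd_first")
    assert a.conv_parameter_count() == b.conv_parameter_count()
    x = rng.normal(size=(1, 2, 5, 5, 5)).astype(np.float32)
    out_a, _ = a(nn.Tensor(x))
    out_b, _ = b(nn.Tensor(x))
    assert out_a.shape == out_b.shape


def test_raw_residual_switch():
    module = LKAttention3d(2, 6, 2, rng=np.random.default_rng(1), residual="raw")
    x = np.random.default_rng(2).normal(size=(1, 2, 5, 5, 5)).astype(np.float32)
    out, a = module(nn.Tensor(x))
    z = module.norm(nn.Tensor(x)).leaky_relu(0.01).data
    np.testing.assert_allclose(out.data, a.data * z + x, atol=1e-6)


def test_original_lk_module_count_and_even_kernel_guard():
    module = OriginalLKAttention3d(8, 5, rng=np.random.default_rng(0))
    assert module.conv_parameter_count() == 8 * (8 * 125 + 1)
    x = np.random.default_rng(1).normal(size=(1, 8, 6, 6, 6)).astype(np.float32)
    out, _ = module(nn.Tensor(x))
    assert out.shape == x.shape
    even = OriginalLKAttention3d(4, 6, rng=np.random.default_rng(0))
    assert even.conv_parameter_count() == 4 * (4 * 216 + 1)
    with pytest.raises(ValueError, match="even"):
        even(nn.Tensor(x[:, :4]))


def test_attention_map_nearest_upsampling():
    a = np.arange(8, dtype=np.float32).reshape(1, 2, 2, 2)
    up = upsample_attention_map(a, (4, 4, 4))
    assert up.shape == (1, 4, 4, 4)
    assert set(np.unique(up)) == set(np.unique(a))
    np.testing.assert_array_equal(up[0, :2, :2, :2], a[0, 0, 0, 0])
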