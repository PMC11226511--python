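"""Autograd engine and 3D convolution primitives.

Forward passes are checked against a naive nested-loop convolution;
gradients are checked by adjointness identities (exact up to float32
round-off) and float64 finite differences on small tensors.
"""

import numpy as np
import pytest

from lka3d import nn
from lka3d.nn import conv as C


def naive_conv3d(x, w, b, stride, pad, dil, groups):
    s, p, d = (stride,) * 3, (pad,) * 3, (dil,) * 3
    N, Cin = x.shape[:2]
    Cout, k = w.shape[0], w.shape[2:]
    xp = np.pad(x, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))
    e = [d[i] * (k[i] - 1) + 1 for i in range(3)]
    out = [(xp.shape[2 + i] - e[i]) // s[i] + 1 for i in range(3)]
    y = np.zeros((N, Cout) + tuple(out))
    cpg, opg = Cin // groups, Cout // groups
    for n in range(N):
        for co in range(Cout):
            for ci in range(cpg):
                ca = (co // opg) * cpg + ci
                for z in range(out[0]):
                    for yy in range(out[1]):
                        for xx in range(out[2]):
                            acc = 0.0
                            for a in range(k[0]):
                                for bb in range(k[1]):
                                    for c in range(k[2]):
                                        acc += (
                                            xp[n, ca, z * s[0] + a * d[0],
                                               yy * s[1] + bb * d[1],
                                               xx * s[2] + c * d[2]]
                                            * w[co, ci, a, bb, c]
                                        )
                            y[n, co, z, yy, xx] += acc
    return y + b.reshape(1, -1, 1, 1, 1)


@pytest.mark.parametrize(
    "cin,cout,k,stride,pad,dil,groups,size",
    [
        (3, 4, 3, 1, 1, 1, 1, 6),
        (2, 5, 3, 2, 1, 1, 1, 8),
        (4, 4, 3, 1, 2, 2, 4, 7),   # depthwise dilated
        (3, 3, 5, 1, 4, 2, 3, 9),   # depthwise, large dilated extent
        (2, 3, 1, 1, 0, 1, 1, 4),   # pointwise
    ],
)
def test_conv_forward_matches_naive(cin, cout, k, stride, pad, dil, groups, size):
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, cin, size, size, size)).astype(np.float32)
    w = rng.normal(size=(cout, cin // groups, k, k, k)).astype(np.float32)
    b = rng.normal(size=cout).astype(np.float32)
    got = C.conv3d_forward(x, w, b, stride, pad, dil, groups)
    want = naive_conv3d(x, w, b, stride, pad, dil, groups)
    np.testing.assert_allclose(got, want, atol=2e-5)


@pytest.mark.parametrize(
    "cin,cout,k,stride,pad,dil,groups,size",
    [
        (2, 3, 3, 1, 1, 1, 1, 5),
        (2, 4, 3, 2, 1, 1, 1, 6),
        (3, 3, 3, 1, 2, 2, 3, 6),
        (2, 3, 4, 2, 2, 1, 1, 7),
    ],
)
def test_conv_gradients_are_adjoint(cin, cout, k, stride, pad, dil, groups, size):
    """<dy, conv(x)> == <data_grad(dy), x> and the directional weight-
    gradient identity — exact linear-algebra checks of the backward pass."""
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2, cin, size, size, size)).astype(np.float32)
    w = rng.normal(size=(cout, cin // groups, k, k, k)).astype(np.float32)
    y = C.conv3d_forward(x, w, None, stride, pad, dil, groups)
    dy = rng.normal(size=y.shape).astype(np.float32)
    dx, dw, db = C.conv3d_backward(x, w, dy, stride, pad, dil, groups)
    lhs = np.vdot(dy.astype(np.float64), y.astype(np.float64))
    rhs = np.vdot(dx.astype(np.float64), x.astype(np.float64))
    assert abs(lhs - rhs) < 1e-4 * abs(lhs)
    wd = rng.normal(size=w.shape).astype(np.float32)
    lhs2 = np.vdot(dy.astype(np.float64),
                   C.conv3d_forward(x, wd, None, stride, pad, dil, groups).astype(np.float64))
    rhs2 = np.vdot(dw.astype(np.float64), wd.astype(np.float64))
    assert abs(lhs2 - rhs2) < 1e-4 * abs(lhs2)
    np.testing.assert_allclose(db, dy.sum(axis=(0, 2, 3, 4)), rtol=1e-4)


@pytest.mark.parametrize("cin,cout,k,stride,pad,size",
                         [(2, 3, 4, 2, 1, 4), (3, 2, 2, 2, 0, 5), (2, 2, 3, 3, 1, 4)])
def test_transposed_conv_shape_and_adjointness(cin, cout, k, stride, pad, size):
    rng = np.random.default_rng(2)
    x = rng.normal(size=(2, cin, size, size, size)).astype(np.float32)
    w = rng.normal(size=(cin, cout, k, k, k)).astype(np.float32)
    y = C.conv_transpose3d_forward(x, w, None, stride, pad)
    expected = (size - 1) * stride - 2 * pad + k
    assert y.shape == (2, cout, expected, expected, expected)
    dy = rng.normal(size=y.shape).astype(np.float32)
    dx, dw, db = C.conv_transpose3d_backward(x, w, dy, stride, pad)
    lhs = np.vdot(dy.astype(np.float64), y.astype(np.float64))
    assert abs(lhs - np.vdot(dx.astype(np.float64), x.astype(np.float64))) < 1e-4 * abs(lhs)
    wd = rng.normal(size=w.shape).astype(np.float32)
    lhs2 = np.vdot(dy.astype(np.float64),
                   C.conv_transpose3d_forward(x, wd, None, stride, pad).astype(np.float64))
    assert abs(lhs2 - np.vdot(dw.astype(np.float64), wd.astype(np.float64))) < 1e-4 * abs(lhs2)


def test_transposed_conv_matches_naive_scatter():
    """Direct oracle: scatter each input voxel's weighted kernel into the
    output, which is the definition of the transposed convolution."""
    rng = np.random.default_rng(3)
    cin, cout, k, s, p, size = 2, 3, 4, 2, 1, 3
    x = rng.normal(size=(1, cin, size, size, size)).astype(np.float32)
    w = rng.normal(size=(cin, cout, k, k, k)).astype(np.float32)
    out = (size - 1) * s - 2 * p + k
    y = np.zeros((1, cout, out + 2 * p, out + 2 * p, out + 2 * p))
    for ci in range(cin):
        for z in range(size):
            for yy in range(size):
                for xx in range(size):
                    y[0, :, z*s:z*s+k, yy*s:yy*s+k, xx*s:xx*s+k] += (
                        x[0, ci, z, yy, xx] * w[ci]
                    )
    y = y[:, :, p:p+out, p:p+out, p:p+out]
    got = C.conv_transpose3d_forward(x, w, None, s, p)
    np.testing.assert_allclose(got, y, atol=2e-5)


def test_group_norm_normalises_and_backpropagates():
    rng = np.random.default_rng(4)
    gn = nn.GroupNorm(6, groups=3)
    x = nn.Tensor(rng.normal(2.0, 3.0, size=(2, 6, 4, 4, 4)), requires_grad=True)
    y = gn(x)
    grouped = y.data.reshape(2, 3, -1)
    np.testing.assert_allclose(grouped.mean(axis=2), 0.0, atol=1e-5)
    np.testing.assert_allclose(grouped.std(axis=2), 1.0, atol=1e-4)
    # finite-difference check of the input gradient in float64 arithmetic
    dy = rng.normal(size=y.shape).astype(np.float32)
    y.backward(dy)
    got = x.grad.copy()

    def f(xd):
        xg = xd.reshape(2, 3, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        xhat = ((xg - mu) / np.sqrt(var + gn.eps)).reshape(xd.shape)
        return float((xhat * dy).sum())

    eps = 1e-5
    xd = x.data.astype(np.float64)
    idxs = [(0, 0, 0, 0, 0), (1, 2, 1, 3, 2), (0, 5, 3, 3, 3), (1, 3, 0, 2, 1)]
    for idx in idxs:
        xp = xd.copy(); xp[idx] += eps
        xm = xd.copy(); xm[idx] -= eps
        num = (f(xp) - f(xm)) / (2 * eps)
        assert got[idx] == pytest.approx(num, rel=1e-3, abs=1e-4)


def test_elementwise_autograd_against_finite_differences():
    rng = np.random.default_rng(5)
    a0 = rng.normal(size=(3, 4)).astype(np.float32)
    b0 = rng.uniform(0.5, 1.5, size=(3, 4)).astype(np.float32)

    def loss_of(a_arr):
        a = nn.Tensor(a_arr, requires_grad=True)
        b = nn.Tensor(b0)
        out = ((a * b + a).sigmoid() * (a - 0.3).leaky_relu(0.01)).sum() \
            + (a * a).mean() + (b / (a.exp() + 1.0)).sum()
        return a, out

    a, out = loss_of(a0)
    out.backward()
    eps = 1e-3
    for idx in [(0, 0), (1, 2), (2, 3)]:
        ap = a0.copy(); ap[idx] += eps
        am = a0.copy(); am[idx] -= eps
        num = (float(loss_of(ap)[1].data) - float(loss_of(am)[1].data)) / (2 * eps)
        assert a.grad[idx] == pytest.approx(num, rel=2e-2, abs=2e-3)


def test_softmax_grad_and_partition_of_unity():
    rng = np.random.default_rng(6)
    x = nn.Tensor(rng.normal(size=(2, 5, 3)), requires_grad=True)
    y = x.softmax(axis=1)
    np.testing.assert_allclose(y.data.sum(axis=1), 1.0, atol=1e-6)
    dy = rng.normal(size=y.shape).astype(np.float32)
    y.backward(dy)
    # gradient rows are orthogonal to the all-ones direction
    np.testing.assert_allclose(x.grad.sum(axis=1), 0.0, atol=1e-5)


def test_no_grad_mode_builds_no_graph():
    x = nn.Tensor(np.ones((2, 2)), requires_grad=True)
    with nn.tensor.no_grad():
        y = (x * 2.0).sum()
    assert y._backward is None and y._prev == ()


def test_adam_minimises_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0]))
    opt = nn.Adam([p], lr=0.2)
    for _ in range(150):
        loss = (p * p).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert np.abs(p.data).max() < 1e-2
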