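"""im2col-based 3D convolution primitives (forward and gradients).

All routines work on float32 arrays shaped (N, C, D, H, W).  Two channel
layouts are supported: dense convolutions (``groups == 1``) and depthwise
convolutions (``groups == C_in == C_out``), which is all the networks in
this package need.  The im2col buffer is filled with one strided copy per
kernel tap and processed in output-depth slabs to bound peak memory; the
transposed convolution is evaluated phase-by-phase on the coarse grid so
no zero-stuffed intermediate is ever materialised.
"""

from __future__ import annotations

import itertools

import numpy as np

# cap on the number of float32 elements in one im2col slab (~256 MB)
_SLAB_ELEMS = 64_000_000

# reused scratch buffers (im2col fills the same pages every call, avoiding
# large-allocation page-fault churn); keyed by role
_scratch: dict[str, np.ndarray] = {}


def _scratch_buf(key: str, shape) -> np.ndarray:
    n = int(np.prod(shape))
    buf = _scratch.get(key)
    if buf is None or buf.size < n:
        buf = np.empty(n, dtype=np.float32)
        _scratch[key] = buf
    return buf[:n].reshape(shape)


def clear_scratch() -> None:
    _scratch.clear()


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or triple, got {v!r}")
    return t


def _pad_spatial(x: np.ndarray, pad) -> np.ndarray:
    if all(p == 0 for p in pad):
        return x
    shape = x.shape[:2] + tuple(x.shape[2 + i] + 2 * pad[i] for i in range(3))
    out = _scratch_buf("pad", shape)
    out.fill(0.0)
    out[:, :, pad[0] : pad[0] + x.shape[2], pad[1] : pad[1] + x.shape[3],
        pad[2] : pad[2] + x.shape[4]] = x
    return out


def _out_size(s: int, e: int, stride: int) -> int:
    o = (s - e) // stride + 1
    if o < 1:
        raise ValueError(f"non-positive conv output size (input {s}, extent {e})")
    return o


def _geometry(xp_shape, k, stride, dil):
    ext = tuple(dil[i] * (k[i] - 1) + 1 for i in range(3))
    out = tuple(_out_size(xp_shape[2 + i], ext[i], stride[i]) for i in range(3))
    return ext, out


def _col_slab(xp, k, stride, dil, z0, z1, oh, ow):
    """im2col for output-depth rows [z0, z1): (N, C, Kv, P), scratch-backed."""
    N, C = xp.shape[:2]
    zd = z1 - z0
    kv = k[0] * k[1] * k[2]
    if kv == 1 and stride == (1, 1, 1):
        # pointwise: the "column" matrix is the input itself
        view = xp[:, :, z0:z1]
        if view.flags.c_contiguous:
            return view.reshape(N, C, 1, zd * oh * ow)
        col = _scratch_buf("col", (N, C, 1, zd, oh, ow))
        col[:, :, 0] = view
        return col.reshape(N, C, 1, zd * oh * ow)
    col = _scratch_buf("col", (N, C, kv, zd, oh, ow))
    sd, sh, sw = stride
    dd, dh, dw = dil
    for t, (a, b, c) in enumerate(itertools.product(range(k[0]), range(k[1]), range(k[2]))):
        col[:, :, t] = xp[
            :, :,
            a * dd + z0 * sd : a * dd + (z1 - 1) * sd + 1 : sd,
            b * dh : b * dh + (oh - 1) * sh + 1 : sh,
            c * dw : c * dw + (ow - 1) * sw + 1 : sw,
        ]
    return col.reshape(N, C, kv, zd * oh * ow)


def _slab_depths(od: int, per_depth_elems: int) -> list[tuple[int, int]]:
    step = max(1, int(_SLAB_ELEMS // max(per_depth_elems, 1)))
    return [(z, min(z + step, od)) for z in range(0, od, step)]


def conv3d_forward(x, w, b, stride=1, pad=0, dil=1, groups=1):
    """Correlate x (N,Cin,D,H,W) with w; returns y (N,Cout,od,oh,ow).

    w is (Cout, Cin, k,k,k) for groups=1 or (C, 1, k,k,k) for depthwise.
    """
    stride, pad, dil = _triple(stride), _triple(pad), _triple(dil)
    N, Cin = x.shape[:2]
    Cout = w.shape[0]
    k = w.shape[2:]
    kv = int(np.prod(k))
    if groups not in (1, Cin) or (groups != 1 and Cout != Cin):
        raise NotImplementedError("only dense (groups=1) and depthwise convs supported")
    xp = _pad_spatial(x, pad)
    _, (od, oh, ow) = _geometry(xp.shape, k, stride, dil)
    y = np.empty((N, Cout, od, oh, ow), dtype=np.float32)
    if groups == 1:
        wm = np.ascontiguousarray(w.reshape(Cout, Cin * kv), dtype=np.float32)
    else:
        wm = np.ascontiguousarray(w.reshape(1, Cin, 1, kv), dtype=np.float32)
    for z0, z1 in _slab_depths(od, N * oh * ow * Cin * kv):
        col = _col_slab(xp, k, stride, dil, z0, z1, oh, ow)
        P = (z1 - z0) * oh * ow
        if groups == 1:
            ysl = _scratch_buf("gemm", (N, Cout, P))
            np.matmul(wm, col.reshape(N, Cin * kv, P), out=ysl)
        else:
            ysl = _scratch_buf("gemm", (N, Cin, 1, P))
            np.matmul(wm, col, out=ysl)
            ysl = ysl[:, :, 0, :]
        y[:, :, z0:z1] = ysl.reshape(N, Cout, z1 - z0, oh, ow)
    if b is not None:
        y += b.reshape(1, Cout, 1, 1, 1)
    return y


def _weight_grad(x, dy, kshape, stride, pad, dil, groups):
    """dL/dw given the conv input x and output gradient dy."""
    stride, pad, dil = _triple(stride), _triple(pad), _triple(dil)
    N, Cin = x.shape[:2]
    Cout = dy.shape[1]
    kv = int(np.prod(kshape))
    xp = _pad_spatial(x, pad)
    _, (od, oh, ow) = _geometry(xp.shape, kshape, stride, dil)
    if groups == 1:
        dw = np.zeros((Cout, Cin * kv), dtype=np.float32)
    else:
        dw = np.zeros((Cin, kv), dtype=np.float32)
    for z0, z1 in _slab_depths(od, N * oh * ow * Cin * kv):
        col = _col_slab(xp, kshape, stride, dil, z0, z1, oh, ow)
        P = (z1 - z0) * oh * ow
        dysl = dy[:, :, z0:z1].reshape(N, Cout, P)
        if groups == 1:
            cols = col.reshape(N, Cin * kv, P)
            dw += np.matmul(dysl, cols.transpose(0, 2, 1)).sum(axis=0)
        else:
            dw += np.matmul(col, dysl[:, :, :, None]).sum(axis=0)[:, :, 0]
    if groups == 1:
        return dw.reshape((Cout, Cin) + tuple(kshape))
    return dw.reshape((Cin, 1) + tuple(kshape))


def _flip_w(w: np.ndarray) -> np.ndarray:
    return w[..., ::-1, ::-1, ::-1]


def _data_grad(dy, w, stride, pad, dil, groups, x_spatial):
    """Gradient w.r.t. the conv input: correlate zero-stuffed dy with the
    flipped (and for dense convs channel-transposed) kernel."""
    stride, pad, dil = _triple(stride), _triple(pad), _triple(dil)
    k = w.shape[2:]
    ext = tuple(dil[i] * (k[i] - 1) + 1 for i in range(3))
    # zero-stuff dy by the stride and border-pad by ext-1, in one buffer
    shape = dy.shape[:2] + tuple(
        (dy.shape[2 + i] - 1) * stride[i] + 1 + 2 * (ext[i] - 1) for i in range(3)
    )
    dyu = _scratch_buf("dilate", shape)
    dyu.fill(0.0)
    dyu[:, :,
        ext[0] - 1 : shape[2] - (ext[0] - 1) : stride[0],
        ext[1] - 1 : shape[3] - (ext[1] - 1) : stride[1],
        ext[2] - 1 : shape[4] - (ext[2] - 1) : stride[2]] = dy
    if groups == 1:
        wt = np.ascontiguousarray(_flip_w(w).transpose(1, 0, 2, 3, 4))
    else:
        wt = np.ascontiguousarray(_flip_w(w))
    dx_full = conv3d_forward(dyu, wt, None, stride=1, pad=0, dil=dil, groups=groups)
    # dx_full covers (od-1)*s + ext of the padded input; right-pad to S + 2p, crop p
    Cx = wt.shape[0] if groups == 1 else dy.shape[1]
    out = np.zeros(
        (dy.shape[0], Cx) + tuple(x_spatial[i] + 2 * pad[i] for i in range(3)),
        dtype=np.float32,
    )
    sl = tuple(slice(0, dx_full.shape[2 + i]) for i in range(3))
    out[(slice(None), slice(None)) + sl] = dx_full
    return out[
        :,
        :,
        pad[0] : pad[0] + x_spatial[0],
        pad[1] : pad[1] + x_spatial[1],
        pad[2] : pad[2] + x_spatial[2],
    ]


def conv3d_backward(x, w, dy, stride=1, pad=0, dil=1, groups=1, need_dx=True):
    """Gradients of conv3d_forward: returns (dx, dw, db)."""
    dw = _weight_grad(x, dy, w.shape[2:], stride, pad, dil, groups)
    db = dy.sum(axis=(0, 2, 3, 4))
    dx = None
    if need_dx:
        dx = _data_grad(dy, w, stride, pad, dil, groups, x.shape[2:])
    return dx, dw, db


# -- transposed convolution (stride-s upsampling, dense only) --------------


def conv_transpose3d_forward(x, w, b, stride=2, pad=1):
    """Transposed conv: x (N,Cin,...), w (Cin,Cout,k,k,k).

    Output spatial size is (S-1)*stride - 2*pad + k.  Each output phase
    (residue of the output index modulo the stride, per axis) only sees a
    fixed arithmetic-progression subset of the kernel taps, so the result
    is assembled from stride^3 small stride-1 convolutions on the coarse
    grid.
    """
    stride, pad = _triple(stride), _triple(pad)
    k = w.shape[2:]
    N, Cin = x.shape[:2]
    Cout = w.shape[1]
    S = x.shape[2:]
    out_sp = tuple((S[i] - 1) * stride[i] - 2 * pad[i] + k[i] for i in range(3))
    if any(o < 1 for o in out_sp):
        raise ValueError(f"non-positive transposed-conv output size {out_sp}")
    y = np.zeros((N, Cout) + out_sp, dtype=np.float32)
    for r in itertools.product(*(range(s) for s in stride)):
        u = [(r[i] + pad[i]) % stride[i] for i in range(3)]
        m = [(r[i] + pad[i]) // stride[i] for i in range(3)]
        T = [len(range(u[i], k[i], stride[i])) for i in range(3)]
        out_len = [max(0, -(-(out_sp[i] - r[i]) // stride[i])) for i in range(3)]
        ysl = (slice(None), slice(None)) + tuple(
            slice(r[i], r[i] + out_len[i] * stride[i], stride[i]) for i in range(3)
        )
        if any(t == 0 for t in T) or any(o == 0 for o in out_len):
            continue
        sub = w[:, :, u[0] :: stride[0], u[1] :: stride[1], u[2] :: stride[2]]
        wt = np.ascontiguousarray(_flip_w(sub).transpose(1, 0, 2, 3, 4))
        # input window covering indices m-(T-1) .. out_len-1+m per axis
        lo = [m[i] - (T[i] - 1) for i in range(3)]
        hi = [out_len[i] - 1 + m[i] for i in range(3)]
        x0 = [max(0, lo[i]) for i in range(3)]
        x1 = [min(S[i] - 1, hi[i]) for i in range(3)]
        pl = [max(0, -lo[i]) for i in range(3)]
        pr = [max(0, hi[i] - (S[i] - 1)) for i in range(3)]
        xs = x[:, :, x0[0] : x1[0] + 1, x0[1] : x1[1] + 1, x0[2] : x1[2] + 1]
        xs = np.pad(xs, ((0, 0), (0, 0)) + tuple((pl[i], pr[i]) for i in range(3)))
        y[ysl] = conv3d_forward(xs, wt, None, stride=1, pad=0)
    if b is not None:
        y += b.reshape(1, Cout, 1, 1, 1)
    return y


def conv_transpose3d_backward(x, w, dy, stride=2, pad=1, need_dx=True):
    """Gradients of the transposed conv.

    The adjoint of upsampling is the plain strided conv, so dx is a
    forward conv of dy with w read channel-swapped; dw is the weight
    gradient of that same conv with the roles of input and output
    gradient exchanged.
    """
    stride, pad = _triple(stride), _triple(pad)
    dw = _weight_grad(dy, x, w.shape[2:], stride, pad, 1, 1)
    db = dy.sum(axis=(0, 2, 3, 4))
    dx = None
    if need_dx:
        dx = conv3d_forward(dy, np.ascontiguousarray(w), None, stride=stride, pad=pad)
    return dx, dw, db
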