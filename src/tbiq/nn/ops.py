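"""Array-level forward/backward primitives (channel-first, no batch axis)."""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv_forward",
    "conv_backward",
    "maxpool_forward",
    "maxpool_backward",
    "upconv_forward",
    "upconv_backward",
    "softmax",
    "softmax_cross_entropy",
]


def _spatial_axes(x):
    return tuple(range(1, x.ndim))


def _kernel_offsets(k):
    from itertools import product

    return list(product(*[range(kk) for kk in k]))


def _offset_slice(off, k, out_sp):
    return tuple(slice(o, o + s) for o, s in zip(off, out_sp))


def _gemm_acc(C, A, B, beta):
    """C = beta*C + A @ B for C-contiguous float32 matrices, in place.

    Uses the identity C^T = B^T A^T on Fortran-ordered transpose views, so
    BLAS accumulates directly into C without temporaries. Falls back to
    numpy for other dtypes.
    """
    if C.dtype == np.float32 and A.dtype == np.float32 and B.dtype == np.float32:
        from scipy.linalg.blas import sgemm

        sgemm(1.0, B.T, A.T, beta=beta, c=C.T, overwrite_c=True)
    else:
        if beta == 0.0:
            np.matmul(A, B, out=C)
        else:
            C += A @ B
    return C


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, padding: str = "valid",
                 cache_slabs: bool = False):
    """Cross-correlation of x (Ci, *sp) with w (Co, Ci, *k) plus bias.

    padding 'valid' shrinks each spatial dim by k-1; 'same' zero-pads to keep
    it (odd kernels only). Computed as a sum over kernel offsets of GEMMs.
    With `cache_slabs` the contiguous input slabs are kept in the cache for
    reuse by conv_backward (trades memory for training speed).
    """
    nd = x.ndim - 1
    k = w.shape[2:]
    if padding == "same":
        pads = [(0, 0)] + [((kk - 1) // 2, (kk - 1) // 2) for kk in k]
        x = np.pad(x, pads)
    elif padding != "valid":
        raise ValueError(padding)
    ci = x.shape[0]
    co = w.shape[0]
    out_sp = tuple(s - kk + 1 for s, kk in zip(x.shape[1:], k))
    n = int(np.prod(out_sp))
    acc = np.zeros((co, n), dtype=x.dtype)
    slabs = [] if cache_slabs else None
    for i, off in enumerate(_kernel_offsets(k)):
        slab = np.ascontiguousarray(x[(slice(None),) + _offset_slice(off, k, out_sp)]).reshape(ci, n)
        if slabs is not None:
            slabs.append(slab)
        w_off = np.ascontiguousarray(w[(slice(None), slice(None)) + off])
        _gemm_acc(acc, w_off, slab, beta=0.0 if i == 0 else 1.0)
    y = acc.reshape((co,) + out_sp)
    y += b.reshape((-1,) + (1,) * nd).astype(x.dtype)
    return y, (x, slabs)


def conv_backward(g: np.ndarray, cache, w: np.ndarray, padding: str = "valid",
                  need_dx: bool = True):
    """Gradients of a conv_forward call. Returns (dx, dw, db).

    `cache` is the (padded input, slabs) pair returned by conv_forward; dx
    is with respect to the original (unpadded) input (None if `need_dx` is
    False, e.g. at the network input).
    """
    x_cached, slabs = cache
    k = w.shape[2:]
    sp_axes = _spatial_axes(g)
    db = g.sum(axis=sp_axes)

    ci = x_cached.shape[0]
    co = g.shape[0]
    out_sp = g.shape[1:]
    n = int(np.prod(out_sp))
    g2 = np.ascontiguousarray(g).reshape(co, n)
    dw = np.empty_like(w)
    dx = np.zeros_like(x_cached) if need_dx else None
    contrib = np.empty((ci, n), dtype=x_cached.dtype) if need_dx else None
    for i, off in enumerate(_kernel_offsets(k)):
        sl = (slice(None),) + _offset_slice(off, k, out_sp)
        if slabs is not None:
            slab = slabs[i]
        else:
            slab = np.ascontiguousarray(x_cached[sl]).reshape(ci, n)
        dw[(slice(None), slice(None)) + off] = g2 @ slab.T
        if need_dx:
            w_off = np.ascontiguousarray(w[(slice(None), slice(None)) + off])
            np.matmul(w_off.T, g2, out=contrib)
            dx[sl] += contrib.reshape((ci,) + tuple(out_sp))
    if need_dx and padding == "same":
        sl = tuple([slice(None)] + [slice((kk - 1) // 2, dx.shape[i + 1] - (kk - 1) // 2)
                                    for i, kk in enumerate(k)])
        dx = np.ascontiguousarray(dx[sl])
    return dx, dw, db


def maxpool_forward(x: np.ndarray):
    """2x max pooling along every spatial axis (sizes must be even)."""
    nd = x.ndim - 1
    c = x.shape[0]
    sp = x.shape[1:]
    if any(s % 2 for s in sp):
        raise ValueError(f"maxpool requires even spatial sizes, got {sp}")
    out_sp = tuple(s // 2 for s in sp)
    shape = (c,) + sum(((s // 2, 2) for s in sp), ())
    xr = x.reshape(shape)
    # move the block axes to the end
    perm = (0,) + tuple(1 + 2 * i for i in range(nd)) + tuple(2 + 2 * i for i in range(nd))
    xr = xr.transpose(perm).reshape((c,) + out_sp + (2**nd,))
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(y), (idx, sp)


def maxpool_backward(g: np.ndarray, cache):
    idx, sp = cache
    nd = g.ndim - 1
    c = g.shape[0]
    out_sp = g.shape[1:]
    buf = np.zeros((c,) + out_sp + (2**nd,), dtype=g.dtype)
    np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
    buf = buf.reshape((c,) + out_sp + (2,) * nd)
    inv = (0,) + sum(((1 + i, 1 + nd + i) for i in range(nd)), ())
    buf = buf.transpose(inv)
    return np.ascontiguousarray(buf.reshape((c,) + sp))


def upconv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Transposed 2x2x2 (stride 2) convolution: doubles every spatial size.

    w has shape (Co, Ci, 2, ..., 2); each kernel offset writes one of the
    2^nd interleaved sub-grids of the output.
    """
    nd = x.ndim - 1
    ci = x.shape[0]
    co = w.shape[0]
    sp = x.shape[1:]
    n = int(np.prod(sp))
    x2 = np.ascontiguousarray(x).reshape(ci, n)
    y = np.empty((co,) + tuple(2 * s for s in sp), dtype=x.dtype)
    for off in _kernel_offsets(w.shape[2:]):
        sl = (slice(None),) + tuple(slice(o, None, 2) for o in off)
        w_off = np.ascontiguousarray(w[(slice(None), slice(None)) + off])
        y[sl] = (w_off @ x2).reshape((co,) + sp)
    y += b.reshape((-1,) + (1,) * nd).astype(x.dtype)
    return y, x2


def upconv_backward(g: np.ndarray, x2_cached: np.ndarray, w: np.ndarray):
    """Gradients of upconv_forward. Returns (dx, dw, db)."""
    nd = g.ndim - 1
    co, ci = w.shape[:2]
    out_sp = g.shape[1:]
    sp = tuple(s // 2 for s in out_sp)
    n = int(np.prod(sp))
    db = g.sum(axis=_spatial_axes(g))
    dw = np.empty_like(w)
    dx2 = np.zeros((ci, n), dtype=g.dtype)
    for off in _kernel_offsets(w.shape[2:]):
        sl = (slice(None),) + tuple(slice(o, None, 2) for o in off)
        g_off = np.ascontiguousarray(g[sl]).reshape(co, n)
        dw[(slice(None), slice(None)) + off] = g_off @ x2_cached.T
        w_off = np.ascontiguousarray(w[(slice(None), slice(None)) + off])
        dx2 += w_off.T @ g_off
    return dx2.reshape((ci,) + sp), dw, db


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean voxelwise cross-entropy; returns (loss, dlogits, probabilities).

    logits: (C, *sp); labels: integer array (*sp).
    """
    p = softmax(logits, axis=0)
    n = labels.size
    flat = p.reshape(p.shape[0], -1)
    lab = labels.reshape(-1)
    eps = 1e-12
    loss = -np.log(flat[lab, np.arange(n)] + eps).mean()
    d = flat.copy()
    d[lab, np.arange(n)] -= 1.0
    d /= n
    return float(loss), d.reshape(p.shape).astype(logits.dtype), p
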