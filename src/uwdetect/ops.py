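"""Spatial operators (convolution, pooling, resampling) with gradients.

All operators follow the same layout conventions as the rest of the
package: activations are ``(B, C, H, W)`` float32 arrays, convolutions use
same-padding ``pad = d*(k-1)//2`` for odd kernels, and pooling layers use
same-padding with the pad value appropriate to the reduction.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autograd import Tensor, _grad_enabled


def _windows(xp: np.ndarray, k: int, stride: int, dilation: int, oh: int, ow: int):
    """Strided (B, C, OH, OW, k, k) view over a padded input."""
    b, c = xp.shape[:2]
    s0, s1, s2, s3 = xp.strides
    return as_strided(
        xp, (b, c, oh, ow, k, k),
        (s0, s1, s2 * stride, s3 * stride, s2 * dilation, s3 * dilation),
        writeable=False)


def out_size(n: int, k: int, stride: int, dilation: int) -> int:
    pad = dilation * (k - 1) // 2
    return (n + 2 * pad - dilation * (k - 1) - 1) // stride + 1


def conv2d(x: Tensor, w: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, dilation: int = 1, groups: int = 1,
           padding: int | None = None) -> Tensor:
    """Grouped 2-D convolution. ``w`` has shape (CO, CI/groups, k, k).

    ``padding=None`` means same-padding ``d*(k-1)//2``; pass an explicit
    value (e.g. 0 for the stride-k aggregation conv) to override.
    """
    b, ci, h, wd = x.data.shape
    co, cig, k, _ = w.data.shape
    if cig * groups != ci:
        raise ValueError(f"channel mismatch: input has {ci} channels, "
                         f"kernel expects {cig * groups}")
    pad = dilation * (k - 1) // 2 if padding is None else padding
    oh = (h + 2 * pad - dilation * (k - 1) - 1) // stride + 1
    ow = (wd + 2 * pad - dilation * (k - 1) - 1) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = _windows(xp, k, stride, dilation, oh, ow)
    g, cog = groups, co // groups
    wing = win.reshape(b, g, cig, oh, ow, k, k)
    wg = w.data.reshape(g, cog, cig, k, k)
    y = np.einsum("bgchwkl,gockl->bgohw", wing, wg, optimize=True)
    y = np.ascontiguousarray(y.reshape(b, co, oh, ow))
    if bias is not None:
        y += bias.data.reshape(1, co, 1, 1)

    out = Tensor(y)
    parents = (x, w) if bias is None else (x, w, bias)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents

        def backward(gout):
            gy = gout.reshape(b, g, cog, oh, ow)
            if bias is not None and bias.requires_grad:
                bias._accum(gout.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.einsum("bgchwkl,bgohw->gockl", wing, gy, optimize=True)
                w._accum(gw.reshape(co, cig, k, k))
            if x.requires_grad:
                gxp = np.zeros_like(xp)
                for kk in range(k):
                    for ll in range(k):
                        t = np.einsum("bgohw,goc->bgchw", gy, wg[:, :, :, kk, ll],
                                      optimize=True)
                        gxp[:, :,
                            kk * dilation: kk * dilation + stride * oh: stride,
                            ll * dilation: ll * dilation + stride * ow: stride,
                            ] += t.reshape(b, ci, oh, ow)
                if pad:
                    gxp = gxp[:, :, pad:-pad, pad:-pad]
                x._accum(gxp)
        out._backward = backward
    return out


def max_pool2d(x: Tensor, k: int, stride: int = 1) -> Tensor:
    """k x k max pooling, same-padding (-inf pad), stride 1 or 2."""
    b, c, h, w = x.data.shape
    pad = (k - 1) // 2
    oh, ow = out_size(h, k, stride, 1), out_size(w, k, stride, 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    win = _windows(xp, k, stride, 1, oh, ow).reshape(b, c, oh, ow, k * k)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = Tensor(np.ascontiguousarray(y))
    if _grad_enabled and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(gout):
            gxp = np.zeros(xp.shape, dtype=np.float32)
            hp, wp = xp.shape[2], xp.shape[3]
            ohg, owg = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
            hi = ohg[None, None] * stride + idx // k      # padded row index
            wi = owg[None, None] * stride + idx % k
            bi = np.arange(b)[:, None, None, None]
            cii = np.arange(c)[None, :, None, None]
            np.add.at(gxp, (bi, cii, hi, wi), gout)
            if pad:
                gxp = gxp[:, :, pad:-pad, pad:-pad]
            x._accum(gxp)
        out._backward = backward
    return out


def avg_pool2d(x: Tensor, k: int, stride: int = 1) -> Tensor:
    """k x k average pooling, same-padding, averaged over the valid window
    (padding is excluded from the divisor, so constants stay constant)."""
    b, c, h, w = x.data.shape
    pad = (k - 1) // 2
    oh, ow = out_size(h, k, stride, 1), out_size(w, k, stride, 1)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = _windows(xp, k, stride, 1, oh, ow)
    ones = np.pad(np.ones((1, 1, h, w), dtype=np.float32),
                  ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    count = _windows(ones, k, stride, 1, oh, ow).sum(axis=(-1, -2))
    y = win.sum(axis=(-1, -2)) / count
    out = Tensor(np.ascontiguousarray(y))
    if _grad_enabled and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(gout):
            gxp = np.zeros(xp.shape, dtype=np.float32)
            gk = gout / count
            for kk in range(k):
                for ll in range(k):
                    gxp[:, :, kk: kk + stride * oh: stride,
                        ll: ll + stride * ow: stride] += gk
            if pad:
                gxp = gxp[:, :, pad:-pad, pad:-pad]
            x._accum(gxp)
        out._backward = backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial dimensions, keeping them as 1 x 1."""
    return x.mean(axis=(2, 3), keepdims=True)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    b, c, h, w = x.data.shape
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor(y)
    if _grad_enabled and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(gout):
            g = gout.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))
            x._accum(g)
        out._backward = backward
    return out
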