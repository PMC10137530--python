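"""Spatial primitives with hand-written backward passes.

Convolution is evaluated as a sum over the k*k kernel offsets, each offset
being a single BLAS-backed channel contraction on a strided view of the
padded input.  This keeps memory flat (no im2col materialisation) while
remaining fast enough for desk-scale forward/backward work on a CPU.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, stack_k

__all__ = ["conv2d", "max_pool2d", "upsample_nearest2", "unfold3x3"]


def _conv_fwd(xp, w, stride, ho, wo, groups):
    n, cin_p = xp.shape[0], xp.shape[1]
    cout, cg, kh, kw = w.shape
    opg = cout // groups
    out = np.zeros((n, cout, ho, wo), dtype=np.float32)
    for g in range(groups):
        xg = xp[:, g * cg : (g + 1) * cg]
        wg = w[g * opg : (g + 1) * opg]
        og = out[:, g * opg : (g + 1) * opg]
        for i in range(kh):
            for j in range(kw):
                xs = xg[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
                og += np.einsum("oc,nchw->nohw", wg[:, :, i, j], xs, optimize=True)
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (C_out, C_in/g, kh, kw)."""
    n, cin, h, w_in = x.shape
    cout, cg, kh, kw = weight.shape
    if cin != cg * groups:
        raise ValueError(f"channel mismatch: input {cin}, weight expects {cg * groups}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w_in + 2 * padding - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("convolution output would be empty")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    out_data = _conv_fwd(xp, weight.data, stride, ho, wo, groups)
    if bias is not None:
        out_data += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._make(out_data, parents, None)

    def bw(g):
        opg = cout // groups
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
            for gi in range(groups):
                xg = xp[:, gi * cg : (gi + 1) * cg]
                gg = g[:, gi * opg : (gi + 1) * opg]
                for i in range(kh):
                    for j in range(kw):
                        xs = xg[:, :, i : i + stride * ho : stride,
                                j : j + stride * wo : stride]
                        gw[gi * opg : (gi + 1) * opg, :, i, j] = np.einsum(
                            "nohw,nchw->oc", gg, xs, optimize=True
                        )
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for gi in range(groups):
                wg = weight.data[gi * opg : (gi + 1) * opg]
                gg = g[:, gi * opg : (gi + 1) * opg]
                tgt = gxp[:, gi * cg : (gi + 1) * cg]
                for i in range(kh):
                    for j in range(kw):
                        tgt[:, :, i : i + stride * ho : stride,
                            j : j + stride * wo : stride] += np.einsum(
                            "nohw,oc->nchw", gg, wg[:, :, i, j], optimize=True
                        )
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    out._backward = bw if out.requires_grad else None
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None,
               padding: int = 0, ceil_mode: bool = False) -> Tensor:
    """Max pooling; padding (and any ceil-mode overhang) is filled with -inf."""
    stride = stride or kernel
    n, c, h, w = x.shape
    if ceil_mode:
        ho = -(-(h + 2 * padding - kernel) // stride) + 1
        wo = -(-(w + 2 * padding - kernel) // stride) + 1
    else:
        ho = (h + 2 * padding - kernel) // stride + 1
        wo = (w + 2 * padding - kernel) // stride + 1
    need_h = (ho - 1) * stride + kernel
    need_w = (wo - 1) * stride + kernel
    pad_b = max(0, need_h - h - padding)
    pad_r = max(0, need_w - w - padding)
    xp = np.pad(
        x.data,
        ((0, 0), (0, 0), (padding, pad_b), (padding, pad_r)),
        constant_values=-np.inf,
    )
    out_data = np.full((n, c, ho, wo), -np.inf, dtype=np.float32)
    for i in range(kernel):
        for j in range(kernel):
            np.maximum(
                out_data,
                xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride],
                out=out_data,
            )
    out = Tensor._make(out_data, (x,), None)

    def bw(g):
        gxp = np.zeros_like(xp)
        claimed = np.zeros(out_data.shape, dtype=bool)
        for i in range(kernel):
            for j in range(kernel):
                xs = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
                m = (xs == out_data) & ~claimed
                claimed |= m
                gxp[:, :, i : i + stride * ho : stride,
                    j : j + stride * wo : stride] += g * m
        x._accum(gxp[:, :, padding : padding + h, padding : padding + w])

    out._backward = bw if out.requires_grad else None
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out = Tensor._make(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,), None)

    def bw(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bw if out.requires_grad else None
    return out


def unfold3x3(x: Tensor) -> Tensor:
    """Gather each pixel's 3x3 neighbourhood: (N,C,H,W) -> (N,C,9,H,W).

    Zero padding at the border; offset order is row-major over the window.
    """
    xp = x.pad2d(1, 1)
    h, w = x.shape[2], x.shape[3]
    slices = [
        xp[:, :, i : i + h, j : j + w] for i in range(3) for j in range(3)
    ]
    return stack_k(slices, axis=2)
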