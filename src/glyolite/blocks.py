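"""Building blocks of the detector family.

The network is assembled from a small vocabulary of blocks referenced by
name from YAML layer tables: the space-to-depth ``Focus`` entry, its
convolutional ``Stem`` replacement (overall stride 4), plain ``Conv``
units, CSP ``C3`` stages, the contextual-transformer ``CoT3`` stage, the
parameter-free ``SimAM`` attention gate, ``SPP`` spatial pyramid pooling,
re-parameterisable ``Rep`` convolutions, and the anchor-based ``Detect``
head.

Every block implements ``profile(c, h, w)`` returning
``(macs, c_out, h_out, w_out)`` so whole-model parameter/FLOP accounting is
analytic (no forward pass needed).  MAC counts cover convolution kernels
and the contextual-attention aggregation; normalisation, activations and
pooling contribute zero, matching the common profiler convention.
"""

from __future__ import annotations

import numpy as np

from . import nn, ops
from .tensor import Tensor, concat

__all__ = [
    "ConvUnit", "Focus", "Stem", "Bottleneck", "C3", "CoT", "CoTBottleneck",
    "CoT3", "SimAM", "SPP", "RepConv", "Concat", "Upsample", "Detect",
    "focus_slice", "focus_unslice",
]


def _rng(rng):
    return rng if rng is not None else np.random.default_rng()


class ConvUnit(nn.Module):
    """Conv2d (no bias) + BatchNorm + activation — the standard conv unit."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act="silu", rng=None):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, p, g, bias=False, rng=_rng(rng))
        self.bn = nn.BatchNorm2d(c2)
        if act == "silu":
            self.act = nn.SiLU()
        elif act == "relu":
            self.act = nn.ReLU()
        elif act is None:
            self.act = nn.Identity()
        else:
            raise ValueError(f"unknown activation {act!r}")

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))

    def profile(self, c, h, w):
        cv = self.conv
        ho = (h + 2 * cv.p - cv.k) // cv.s + 1
        wo = (w + 2 * cv.p - cv.k) // cv.s + 1
        macs = cv.k * cv.k * (cv.c1 // cv.g) * cv.c2 * ho * wo
        return macs, cv.c2, ho, wo


def focus_slice(x: Tensor) -> Tensor:
    """Space-to-depth: (H, W, C) -> (H/2, W/2, 4C).

    The four pixel lattices are stacked along channels in the fixed order
    (even row, even col), (odd, even), (even, odd), (odd, odd).  The map is
    a bijection: :func:`focus_unslice` reconstructs the input exactly.
    """
    h, w = x.shape[2], x.shape[3]
    if h % 2 or w % 2:
        raise ValueError(f"focus slicing needs even spatial dims, got {h}x{w}")
    return concat(
        [
            x[:, :, ::2, ::2],
            x[:, :, 1::2, ::2],
            x[:, :, ::2, 1::2],
            x[:, :, 1::2, 1::2],
        ],
        axis=1,
    )


def focus_unslice(y) -> np.ndarray:
    """Inverse of :func:`focus_slice` (ndarray in, ndarray out)."""
    y = y.data if isinstance(y, Tensor) else np.asarray(y)
    n, c4, h, w = y.shape
    c = c4 // 4
    out = np.empty((n, c, 2 * h, 2 * w), dtype=y.dtype)
    out[:, :, ::2, ::2] = y[:, :c]
    out[:, :, 1::2, ::2] = y[:, c : 2 * c]
    out[:, :, ::2, 1::2] = y[:, 2 * c : 3 * c]
    out[:, :, 1::2, 1::2] = y[:, 3 * c :]
    return out


class Focus(nn.Module):
    """Space-to-depth slicing followed by a conv unit; overall stride 2."""

    def __init__(self, c1, c2, k=3, rng=None):
        super().__init__()
        self.cv = ConvUnit(4 * c1, c2, k, 1, rng=rng)

    def forward(self, x):
        return self.cv(focus_slice(x))

    def profile(self, c, h, w):
        return self.cv.profile(4 * c, h // 2, w // 2)


class Stem(nn.Module):
    """Convolutional entry stage, overall stride 4.

    A 3x3/s2 conv for rapid downsampling, then two parallel branches — a
    1x1 -> 3x3/s2 conv pair and a 2x2/s2 max-pool — concatenated and
    projected back to ``c2`` channels by a 1x1 conv.
    """

    def __init__(self, c1, c2, k=3, rng=None):
        super().__init__()
        self.cv1 = ConvUnit(c1, c2, k, 2, rng=rng)
        self.branch_a = ConvUnit(c2, c2 // 2, 1, 1, rng=rng)
        self.branch_b = ConvUnit(c2 // 2, c2, k, 2, rng=rng)
        self.pool = nn.MaxPool2d(2, 2, 0, ceil_mode=True)
        self.proj = ConvUnit(2 * c2, c2, 1, 1, rng=rng)

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        if h % 4 or w % 4:
            raise ValueError(f"stem needs spatial dims divisible by 4, got {h}x{w}")
        y = self.cv1(x)
        conv_path = self.branch_b(self.branch_a(y))
        pool_path = self.pool(y)
        return self.proj(concat([conv_path, pool_path], axis=1))

    def profile(self, c, h, w):
        m1, c_, h2, w2 = self.cv1.profile(c, h, w)
        ma, ca, _, _ = self.branch_a.profile(c_, h2, w2)
        mb, cb, h4, w4 = self.branch_b.profile(ca, h2, w2)
        mp, cp, _, _ = self.proj.profile(cb + c_, h4, w4)
        return m1 + ma + mb + mp, cp, h4, w4


class Bottleneck(nn.Module):
    def __init__(self, c1, c2, shortcut=True, e=1.0, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvUnit(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvUnit(c_, c2, 3, 1, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def profile(self, c, h, w):
        m1, c_, h, w = self.cv1.profile(c, h, w)
        m2, c2, h, w = self.cv2.profile(c_, h, w)
        return m1 + m2, c2, h, w


class CoT(nn.Module):
    """Contextual-transformer attention on a feature map, output shape = input.

    Keys pass a k x k group convolution producing the static context; the
    attention matrix comes from two consecutive 1x1 convolutions on the
    concatenated (static context, query) stack (channel count doubles at the
    concat); values are aggregated over each k x k neighbourhood with
    softmax-normalised weights (the local matrix multiplication); the output
    fuses static and dynamic context by addition.
    """

    GROUPS = 4
    REDUCTION = 4

    def __init__(self, dim, k=3, rng=None):
        super().__init__()
        if k % 2 == 0:
            raise ValueError(f"contextual kernel must be odd, got {k}")
        if k != 3:
            raise ValueError("only k=3 neighbourhood aggregation is implemented")
        if dim % self.GROUPS:
            raise ValueError(f"dim={dim} not divisible by groups={self.GROUPS}")
        self.dim, self.k = dim, k
        red = max(2 * dim // self.REDUCTION, 1)
        self.key_embed = ConvUnit(dim, dim, k, 1, g=self.GROUPS, act="relu", rng=rng)
        # value embedding: a plain linear 1x1 map (no norm, no bias)
        self.value_embed = nn.Conv2d(dim, dim, 1, bias=False, rng=_rng(rng))
        self.attn_reduce = ConvUnit(2 * dim, red, 1, 1, act="relu", rng=rng)
        self.attn_expand = nn.Conv2d(red, k * k * dim, 1, bias=False, rng=_rng(rng))

    def forward(self, x):
        n, c, h, w = x.shape
        k_static = self.key_embed(x)
        v = self.value_embed(x)
        att = self.attn_expand(self.attn_reduce(concat([k_static, x], axis=1)))
        att = att.reshape(n, self.dim, self.k * self.k, h, w)
        weights = att.softmax(axis=2)
        k_dynamic = (weights * ops.unfold3x3(v)).sum(axis=2)
        return k_static + k_dynamic

    def profile(self, c, h, w):
        m, _, _, _ = self.key_embed.profile(c, h, w)
        m += self.dim * self.dim * h * w                      # value embed 1x1
        m += 2 * self.dim * self.attn_reduce.conv.c2 * h * w  # attention reduce
        m += self.attn_reduce.conv.c2 * self.k * self.k * self.dim * h * w
        m += self.k * self.k * self.dim * h * w               # local aggregation
        return m, self.dim, h, w


class CoTBottleneck(nn.Module):
    def __init__(self, c1, c2, shortcut=True, rng=None):
        super().__init__()
        self.cv1 = ConvUnit(c1, c2, 1, 1, rng=rng)
        self.cot = CoT(c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cot(self.cv1(x))
        return x + y if self.add else y

    def profile(self, c, h, w):
        m1, c_, h, w = self.cv1.profile(c, h, w)
        m2, c2, h, w = self.cot.profile(c_, h, w)
        return m1 + m2, c2, h, w


class _CSPStage(nn.Module):
    """Cross-stage-partial split/merge wrapper shared by C3 and CoT3."""

    inner = Bottleneck

    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5, rng=None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = ConvUnit(c1, c_, 1, 1, rng=rng)
        self.cv2 = ConvUnit(c1, c_, 1, 1, rng=rng)
        self.cv3 = ConvUnit(2 * c_, c2, 1, 1, rng=rng)
        self.m = nn.Sequential(
            *(type(self).inner(c_, c_, shortcut, rng=rng) for _ in range(n))
        )

    def forward(self, x):
        return self.cv3(concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))

    def profile(self, c, h, w):
        m1, c_, h, w = self.cv1.profile(c, h, w)
        m2 = self.cv2.profile(c, h, w)[0]
        total = m1 + m2
        for blk in self.m.mods:
            mb, c_, h, w = blk.profile(c_, h, w)
            total += mb
        m3, c2, h, w = self.cv3.profile(2 * c_, h, w)
        return total + m3, c2, h, w


class C3(_CSPStage):
    inner = Bottleneck


class CoT3(_CSPStage):
    inner = CoTBottleneck


class SimAM(nn.Module):
    """Parameter-free attention: gates each neuron by its inverse minimal energy.

    Each neuron t competes against the M-1 other neurons of its channel
    through a regularised linear-separation energy; the closed-form minimum
    is e* = 4 (s^2 + lambda) / ((t - mu)^2 + 2 s^2 + 2 lambda), where mu and
    s^2 are the mean and variance of the *other* neurons.  The gate is the
    logistic of the inverse energy, multiplied into the input.  The exact
    leave-one-out statistics are computed from channel aggregates, so the
    layer is O(HW) and adds zero learnable parameters.  (For large M this
    coincides with the common shared-statistics approximation.)
    """

    def __init__(self, lam: float = 1e-4):
        super().__init__()
        if lam <= 0:
            raise ValueError(f"lambda must be positive, got {lam}")
        self.lam = lam

    def forward(self, x):
        h, w = x.shape[2], x.shape[3]
        m = h * w
        if m < 2:
            raise ValueError("SimAM needs at least 2 neurons per channel")
        s1 = x.sum(axis=(2, 3), keepdims=True)
        s2 = (x * x).sum(axis=(2, 3), keepdims=True)
        mu = (s1 - x) * (1.0 / (m - 1))                       # leave-one-out mean
        var = ((s2 - x * x) * (1.0 / (m - 1)) - mu * mu).maximum(0.0)
        inv_energy = ((x - mu) ** 2 + 2.0 * var + 2.0 * self.lam) / (
            4.0 * (var + self.lam)
        )
        return x * inv_energy.sigmoid()

    def profile(self, c, h, w):
        return 0, c, h, w


class SPP(nn.Module):
    """Spatial pyramid pooling with parallel max-pools and identity path."""

    def __init__(self, c1, c2, ks=(5, 9, 13), rng=None):
        super().__init__()
        for k in ks:
            if k % 2 == 0:
                raise ValueError(f"SPP kernels must be odd, got {ks}")
        c_ = c1 // 2
        self.cv1 = ConvUnit(c1, c_, 1, 1, rng=rng)
        self.pools = [nn.MaxPool2d(k, 1, k // 2) for k in ks]
        self.cv2 = ConvUnit(c_ * (len(ks) + 1), c2, 1, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        return self.cv2(concat([y] + [p(y) for p in self.pools], axis=1))

    def profile(self, c, h, w):
        m1, c_, h, w = self.cv1.profile(c, h, w)
        m2, c2, h, w = self.cv2.profile(c_ * (len(self.pools) + 1), h, w)
        return m1 + m2, c2, h, w


class RepConv(nn.Module):
    """Re-parameterisable conv: multi-branch in training, single 3x3 deployed.

    Training branches: dense 3x3 conv + BN, 1x1 conv + BN, and (only when
    input channels == output channels and stride 1) an identity BN branch.
    ``fuse()`` collapses the block; see :mod:`glyolite.reparam`.
    """

    def __init__(self, c1, c2, k=3, s=1, rng=None):
        super().__init__()
        if k != 3:
            raise ValueError("rep blocks are defined for 3x3 kernels")
        self.c1, self.c2, self.s = c1, c2, s
        rng = _rng(rng)
        self.dense = nn.Conv2d(c1, c2, 3, s, 1, bias=False, rng=rng)
        self.dense_bn = nn.BatchNorm2d(c2)
        self.one = nn.Conv2d(c1, c2, 1, s, 0, bias=False, rng=rng)
        self.one_bn = nn.BatchNorm2d(c2)
        self.id_bn = nn.BatchNorm2d(c2) if (c1 == c2 and s == 1) else None
        self.act = nn.SiLU()
        self.fused = None  # set by reparam.collapse into deploy mode

    @property
    def deployed(self) -> bool:
        return self.fused is not None

    def branch_sum(self, x):
        y = self.dense_bn(self.dense(x)) + self.one_bn(self.one(x))
        if self.id_bn is not None:
            y = y + self.id_bn(x)
        return y

    def forward(self, x):
        if self.deployed:
            return self.act(self.fused(x))
        return self.act(self.branch_sum(x))

    def children(self):
        if self.deployed:
            yield "fused", self.fused
            return
        yield from super().children()

    def profile(self, c, h, w):
        ho = (h + 2 - 3) // self.s + 1
        wo = (w + 2 - 3) // self.s + 1
        macs = 9 * self.c1 * self.c2 * ho * wo
        if not self.deployed:
            macs += self.c1 * self.c2 * ho * wo
        return macs, self.c2, ho, wo


class Concat(nn.Module):
    def __init__(self, axis=1):
        super().__init__()
        self.axis = axis

    def forward(self, xs):
        return concat(xs, axis=self.axis)

    def profile(self, shapes):
        c = sum(s[0] for s in shapes)
        return 0, c, shapes[0][1], shapes[0][2]


class Upsample(nn.Module):
    def __init__(self, size=None, scale=2, mode="nearest"):
        super().__init__()
        if scale != 2 or mode != "nearest":
            raise ValueError("only 2x nearest upsampling is supported")

    def forward(self, x):
        return ops.upsample_nearest2(x)

    def profile(self, c, h, w):
        return 0, c, 2 * h, 2 * w


class Detect(nn.Module):
    """Anchor-based detection head: one 1x1 conv per scale.

    Raw outputs are returned as (N, n_anchors, H, W, 5 + nc) tensors per
    scale; decoding to boxes lives in :mod:`glyolite.model`.
    """

    def __init__(self, nc, anchors, ch, rng=None):
        super().__init__()
        self.nc = nc
        self.no = nc + 5
        self.na = len(anchors[0]) // 2
        self.nl = len(anchors)
        self.anchors = np.asarray(anchors, dtype=np.float32).reshape(self.nl, self.na, 2)
        self.strides = None  # filled by the model builder
        self.m = [nn.Conv2d(c, self.no * self.na, 1, bias=True, rng=_rng(rng)) for c in ch]

    def initialize_biases(self, strides):
        """Prior-aware bias init: low objectness, uniform class probabilities."""
        self.strides = np.asarray(strides, dtype=np.float32)
        for conv, s in zip(self.m, self.strides):
            b = conv.bias.data.reshape(self.na, self.no)
            b[:, 4] += np.log(8.0 / (640.0 / s) ** 2)
            b[:, 5:] += np.log(0.6 / max(self.nc - 0.99, 0.01)) if self.nc > 1 else 0.0
            conv.bias.data = b.reshape(-1)

    def forward(self, xs):
        out = []
        for conv, x in zip(self.m, xs):
            n, _, h, w = x.shape
            y = conv(x).reshape(n, self.na, self.no, h, w)
            out.append(y.transpose(0, 1, 3, 4, 2))
        return out

    def profile(self, shapes):
        macs = sum(
            c * self.no * self.na * h * w for (c, h, w) in shapes
        )
        return macs, self.no * self.na, shapes[-1][1], shapes[-1][2]
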