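"""Analytic parameter and FLOP accounting.

Two counting conventions are exposed, because the literature mixes them:

* **Convention A** (the closed-form conv calculus): a convolution with an
  ``h x w x c`` kernel and ``n`` output channels has ``n * (h*w*c + 1)``
  parameters, and costs ``H * W * n * (h*w*c + 1)`` operations on an
  ``H x W`` output map — one op per multiply-accumulate plus one per bias
  add.
* **Convention B** (profiler convention): two ops per multiply-accumulate
  over conv kernels and the contextual-attention aggregation; bias,
  normalisation, activations and pooling count zero.  Whole-model GFLOPs
  in the shipped tables use this convention at 640 x 640.

``profile_model`` reports per-layer and total parameters and both FLOP
conventions; parameter totals reflect the model's current mode (so a
re-parameterised deploy model reports its fused counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import blocks
from .model import Model

__all__ = ["ConvUnitSpec", "count_parameters", "count_flops",
           "LayerProfile", "ProfileReport", "profile_model"]


@dataclass(frozen=True)
class ConvUnitSpec:
    """A bare convolution spec for the closed-form calculus."""

    h: int                  # kernel height
    w: int                  # kernel width
    c: int                  # input channels
    n: int                  # output channels
    stride: int = 1
    has_bias: bool = True

    def __post_init__(self):
        if min(self.h, self.w, self.stride) < 1 or min(self.c, self.n) < 1:
            raise ValueError(f"invalid conv spec {self}")


def count_parameters(obj) -> int:
    """Parameters of a conv spec (``n*(h*w*c+1)``) or of a whole model."""
    if isinstance(obj, ConvUnitSpec):
        return obj.n * (obj.h * obj.w * obj.c + 1)
    return obj.num_parameters()


def count_flops(spec: ConvUnitSpec, out_h: int, out_w: int) -> int:
    """Convention-A FLOPs: ``H * W * n * (h*w*c + 1)``."""
    if out_h < 1 or out_w < 1:
        raise ValueError("output dims must be >= 1")
    return out_h * out_w * spec.n * (spec.h * spec.w * spec.c + 1)


@dataclass
class LayerProfile:
    index: int
    name: str
    params: int
    macs: int

    @property
    def flops_2x(self) -> int:
        return 2 * self.macs


@dataclass
class ProfileReport:
    img_size: int
    layers: list = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(l.params for l in self.layers)

    @property
    def total_macs(self) -> int:
        return sum(l.macs for l in self.layers)

    @property
    def params_millions(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def gflops(self) -> float:
        """Convention-B GFLOPs (2 ops per MAC) at the profiled input size."""
        return round(2 * self.total_macs / 1e9, 1)

    def __str__(self):
        lines = [f"{'idx':>4} {'module':<12} {'params':>10} {'MACs':>14}"]
        for l in self.layers:
            lines.append(f"{l.index:>4} {l.name:<12} {l.params:>10} {l.macs:>14}")
        lines.append(
            f"total: {self.total_params} params ({self.params_millions} M), "
            f"{self.gflops} GFLOPs @ {self.img_size}"
        )
        return "\n".join(lines)


def profile_model(model: Model, img_size: int = 640) -> ProfileReport:
    """Per-layer analytic parameter/MAC report at a square input size."""
    if img_size % 64:
        raise ValueError("input size must be divisible by the maximum stride (64)")
    report = ProfileReport(img_size)
    cur = (3, img_size, img_size)
    shapes = []
    for i, (m, f) in enumerate(zip(model.layers, model.layers_from)):
        if isinstance(m, (blocks.Concat, blocks.Detect)):
            ins = [cur if j == -1 else shapes[j] for j in f]
            macs, c, h, w = m.profile(ins)
        else:
            c_in, h_in, w_in = cur if f[0] == -1 else shapes[f[0]]
            macs, c, h, w = m.profile(c_in, h_in, w_in)
        cur = (c, h, w)
        shapes.append(cur)
        report.layers.append(
            LayerProfile(i, type(m).__name__, m.num_parameters(), macs)
        )
    return report
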