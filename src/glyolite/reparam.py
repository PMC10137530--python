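"""Structural re-parameterisation: collapse multi-branch rep blocks.

A rep block trains with parallel dense-3x3, 1x1 and (shape permitting)
identity branches, each followed by batch norm.  For inference the block
is algebraically collapsed into a single 3x3 convolution with bias whose
pre-activation output equals the sum of the branch outputs exactly (up to
float round-off):

* conv followed by BN folds into one conv:  w' = w * gamma / sqrt(var+eps),
  b' = beta - gamma * mean / sqrt(var+eps)  (plus the scaled original bias);
* a 1x1 kernel pads to 3x3 with its weight at the centre;
* an identity branch is a centred unit 3x3 kernel per channel, BN-folded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import RepConv
from .tensor import Tensor, no_grad

__all__ = ["FusedConv", "fuse_conv_bn", "collapse_rep_block",
           "convert_model_to_deploy", "equivalence_report"]


@dataclass
class FusedConv:
    weight: np.ndarray  # (c2, c1, 3, 3)
    bias: np.ndarray    # (c2,)
    stride: int

    def to_module(self, rng=None) -> nn.Conv2d:
        c2, c1 = self.weight.shape[:2]
        m = nn.Conv2d(c1, c2, 3, self.stride, 1, bias=True,
                      rng=np.random.default_rng(0))
        m.weight.data = self.weight.astype(np.float32)
        m.bias.data = self.bias.astype(np.float32)
        return m


def fuse_conv_bn(conv_weight: np.ndarray, bn: nn.BatchNorm2d,
                 conv_bias: np.ndarray | None = None, stride: int = 1) -> FusedConv:
    """Fold a conv -> BN pair into a single conv with bias.

    Uses the BN's running statistics, so the fusion matches the pair in
    eval mode on every input.
    """
    var = bn.running_var + bn.eps
    if np.any(var <= 0):
        raise FloatingPointError("non-positive BN variance")
    scale = bn.weight.data / np.sqrt(var)
    w = conv_weight * scale[:, None, None, None]
    b = bn.bias.data - scale * bn.running_mean
    if conv_bias is not None:
        b = b + scale * conv_bias
    return FusedConv(w.astype(np.float32), b.astype(np.float32), stride)


def _pad_1x1_to_3x3(w: np.ndarray) -> np.ndarray:
    out = np.zeros((w.shape[0], w.shape[1], 3, 3), dtype=w.dtype)
    out[:, :, 1, 1] = w[:, :, 0, 0]
    return out


def _identity_kernel(c: int) -> np.ndarray:
    w = np.zeros((c, c, 3, 3), dtype=np.float32)
    w[np.arange(c), np.arange(c), 1, 1] = 1.0
    return w


def collapse_rep_block(block: RepConv) -> FusedConv:
    """Collapse a rep block's branches into one equivalent 3x3 conv."""
    dense = fuse_conv_bn(block.dense.weight.data, block.dense_bn, stride=block.s)
    one = fuse_conv_bn(block.one.weight.data, block.one_bn, stride=block.s)
    w = dense.weight + _pad_1x1_to_3x3(one.weight)
    b = dense.bias + one.bias
    if block.id_bn is not None:
        if block.c1 != block.c2 or block.s != 1:
            raise ValueError("identity branch requires matching channels, stride 1")
        ident = fuse_conv_bn(_identity_kernel(block.c1), block.id_bn, stride=1)
        w = w + ident.weight
        b = b + ident.bias
    return FusedConv(w, b, block.s)


def convert_model_to_deploy(model):
    """Replace every rep block in the model by its fused conv, in place.

    Idempotent: a second call is a no-op; a model without rep blocks is
    returned unchanged.
    """
    for m in model.modules():
        if isinstance(m, RepConv) and not m.deployed:
            m.fused = collapse_rep_block(m).to_module()
    return model


def equivalence_report(model, img_size: int = 640, seed: int = 0) -> dict:
    """Numerically certify train/deploy output equivalence on a random input.

    Runs the model once with branches and once fused (converting if
    necessary) and reports the max abs deviation over all detection logits
    plus parameter counts before/after.
    """
    rng = np.random.default_rng(seed)
    x = Tensor(rng.standard_normal((1, 3, img_size, img_size)).astype(np.float32))
    model.eval()
    reps = [m for m in model.modules() if isinstance(m, RepConv)]
    restore = [(m, m.fused) for m in reps]
    for m in reps:
        m.fused = None
    params_before = model.num_parameters()
    with no_grad():
        ref = model(x)
    for m, fused in restore:
        m.fused = fused
    convert_model_to_deploy(model)
    params_after = model.num_parameters()
    with no_grad():
        out = model(x)
    ref_list = ref if isinstance(ref, list) else [ref]
    out_list = out if isinstance(out, list) else [out]
    max_dev = max(
        float(np.abs(a.data - b.data).max()) for a, b in zip(ref_list, out_list)
    )
    return {
        "max_abs_deviation": max_dev,
        "params_training": int(params_before),
        "params_deploy": int(params_after),
        "n_rep_blocks": len(reps),
        "img_size": img_size,
    }
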