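"""Training objective: BCE classification/objectness + complete-IoU box term.

The classification and objectness terms use natural-log binary
cross-entropy, Loss(g, p) = -g ln p - (1-g) ln(1-p); the box-regression
term uses the complete-IoU form with the baseline framework's per-scale
objectness balance weights.  Target assignment follows the across-grid
convention: a ground-truth box matches an anchor when the width/height
ratio is within ``anchor_t`` in both directions, and is assigned to its
cell plus up to two neighbouring cells.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, concat

__all__ = ["bce", "bce_logits", "ciou", "build_targets", "DetectionLoss"]

EPS = 1e-7


def bce(g, p, eps: float = EPS):
    """Elementwise natural-log binary cross-entropy on probabilities.

    ``g`` must be in {0, 1}; ``p`` is clamped to [eps, 1-eps].  Arrays
    reduce by mean.
    """
    g = np.asarray(g, dtype=np.float64)
    if not np.all((g == 0) | (g == 1)):
        raise ValueError("true labels must be 0 or 1")
    p = np.clip(np.asarray(p, dtype=np.float64), eps, 1 - eps)
    loss = -g * np.log(p) - (1 - g) * np.log(1 - p)
    return float(loss.mean())


def _softplus(x: Tensor) -> Tensor:
    # log(1 + e^x) computed stably as max(x,0) + log(1 + e^-|x|)
    ax = x.maximum(-x)
    return x.maximum(0.0) + ((-ax).exp() + 1.0).log()


def bce_logits(logits: Tensor, targets) -> Tensor:
    """Mean natural-log BCE on raw logits: softplus(x) - t*x, elementwise."""
    t = np.asarray(targets, dtype=np.float32)
    return (_softplus(logits) - logits * Tensor(t)).mean()


def ciou(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Complete IoU between predicted and target boxes in (cx, cy, w, h).

    ``pred`` is an (n, 4) tensor; ``target`` an (n, 4) array.  Returns an
    (n,) tensor of CIoU values.
    """
    t = Tensor(np.asarray(target, dtype=np.float32))
    px1, px2 = pred[:, 0] - pred[:, 2] * 0.5, pred[:, 0] + pred[:, 2] * 0.5
    py1, py2 = pred[:, 1] - pred[:, 3] * 0.5, pred[:, 1] + pred[:, 3] * 0.5
    tx1, tx2 = t[:, 0] - t[:, 2] * 0.5, t[:, 0] + t[:, 2] * 0.5
    ty1, ty2 = t[:, 1] - t[:, 3] * 0.5, t[:, 1] + t[:, 3] * 0.5
    iw = (px2.minimum(tx2) - px1.maximum(tx1)).maximum(0.0)
    ih = (py2.minimum(ty2) - py1.maximum(ty1)).maximum(0.0)
    inter = iw * ih
    union = pred[:, 2] * pred[:, 3] + t[:, 2] * t[:, 3] - inter + eps
    iou = inter / union
    # enclosing box diagonal and centre distance
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw * cw + ch * ch + eps
    rho2 = (pred[:, 0] - t[:, 0]) ** 2 + (pred[:, 1] - t[:, 1]) ** 2
    v = (4.0 / math.pi**2) * (
        (pred[:, 2] / (pred[:, 3] + eps)).arctan()
        - Tensor(np.arctan(target[:, 2] / (target[:, 3] + eps)).astype(np.float32))
    ) ** 2
    with_alpha = v.data / (1.0 - iou.data + v.data + eps)  # detached weighting
    return iou - rho2 / c2 - v * Tensor(with_alpha)


def build_targets(targets: np.ndarray, anchors: np.ndarray, strides,
                  grids, anchor_t: float = 4.0):
    """Assign ground-truth boxes to anchors and cells per scale.

    ``targets``: (n, 6) array of (image, class, cx, cy, w, h), normalised.
    Returns per scale a dict of index arrays and regression targets.
    """
    out = []
    nt = len(targets)
    for level, (stride, (gh, gw)) in enumerate(zip(strides, grids)):
        a = anchors[level] / stride  # anchor sizes in grid units
        if nt == 0:
            out.append(None)
            continue
        t = targets.copy()
        t[:, 2] *= gw
        t[:, 4] *= gw
        t[:, 3] *= gh
        t[:, 5] *= gh
        # anchor matching by wh ratio
        rows = []
        for ai in range(len(a)):
            r = t[:, 4:6] / a[ai]
            ok = np.maximum(r, 1.0 / r).max(axis=1) < anchor_t
            sel = t[ok]
            if len(sel):
                rows.append(
                    np.concatenate(
                        [sel, np.full((len(sel), 1), ai, dtype=np.float64)], axis=1
                    )
                )
        if not rows:
            out.append(None)
            continue
        t = np.concatenate(rows, 0)
        # neighbour-cell duplication (offset 0.5)
        gxy = t[:, 2:4]
        frac = gxy % 1.0
        left = (frac[:, 0] < 0.5) & (gxy[:, 0] > 1)
        top = (frac[:, 1] < 0.5) & (gxy[:, 1] > 1)
        right = (frac[:, 0] >= 0.5) & (gxy[:, 0] < gw - 1)
        bottom = (frac[:, 1] >= 0.5) & (gxy[:, 1] < gh - 1)
        offsets = [np.zeros((len(t), 2))]
        masks = [np.ones(len(t), dtype=bool)]
        for mask, off in [
            (left, (-0.5, 0)), (top, (0, -0.5)), (right, (0.5, 0)), (bottom, (0, 0.5)),
        ]:
            masks.append(mask)
            offsets.append(np.tile(off, (len(t), 1)))
        t_all, off_all = [], []
        for m, off in zip(masks, offsets):
            t_all.append(t[m])
            off_all.append(off[m])
        t = np.concatenate(t_all, 0)
        off = np.concatenate(off_all, 0)
        cell = (t[:, 2:4] - off).astype(int)
        cell[:, 0] = cell[:, 0].clip(0, gw - 1)
        cell[:, 1] = cell[:, 1].clip(0, gh - 1)
        out.append(
            {
                "img": t[:, 0].astype(int),
                "anchor": t[:, 6].astype(int),
                "gj": cell[:, 1],
                "gi": cell[:, 0],
                "txy": t[:, 2:4] - cell,      # target offset within cell, in (-0.5, 1.5)
                "twh": t[:, 4:6],
                "cls": t[:, 1].astype(int),
                "anchor_wh": a[t[:, 6].astype(int)],
            }
        )
    return out


class DetectionLoss:
    """Composed detection objective with per-component reporting."""

    BALANCE = (4.0, 1.0, 0.4)

    def __init__(self, model, box_w: float = 0.05, obj_w: float = 1.0,
                 cls_w: float = 0.5, anchor_t: float = 4.0):
        det = model.detect
        if det is None or det.strides is None:
            raise ValueError("model has no anchored detection head")
        self.nc = det.nc
        self.anchors = det.anchors
        self.strides = det.strides
        self.box_w, self.obj_w, self.cls_w = box_w, obj_w, cls_w
        self.anchor_t = anchor_t

    def __call__(self, raw, targets: np.ndarray):
        """``raw``: per-scale (N, na, H, W, 5+nc) tensors; ``targets`` (n, 6)."""
        grids = [(r.shape[2], r.shape[3]) for r in raw]
        assigned = build_targets(
            np.asarray(targets, dtype=np.float64).reshape(-1, 6),
            self.anchors, self.strides, grids, self.anchor_t,
        )
        lbox = Tensor(0.0)
        lcls = Tensor(0.0)
        lobj = Tensor(0.0)
        n_pos = 0
        for level, (r, t) in enumerate(zip(raw, assigned)):
            n, na, gh, gw, no = r.shape
            obj_target = np.zeros((n, na, gh, gw), dtype=np.float32)
            if t is not None and len(t["img"]):
                idx = (t["img"], t["anchor"], t["gj"], t["gi"])
                pred = r[idx]  # (m, 5+nc)
                pxy = pred[:, 0:2].sigmoid() * 2.0 - 0.5
                pwh = (pred[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(
                    t["anchor_wh"].astype(np.float32)
                )
                pbox = concat([pxy, pwh], axis=1)
                tbox = np.concatenate([t["txy"], t["twh"]], axis=1)
                iou = ciou(pbox, tbox)
                lbox = lbox + (1.0 - iou).mean()
                obj_target[idx] = np.clip(iou.data, 0, None)
                # class term is kept even for a single class so that the
                # decoded confidence sig(obj)*sig(cls) is calibrated
                cls_t = np.zeros((len(t["cls"]), self.nc), dtype=np.float32)
                cls_t[np.arange(len(t["cls"])), t["cls"]] = 1.0
                lcls = lcls + bce_logits(pred[:, 5:], cls_t)
                n_pos += len(t["img"])
            lobj = lobj + bce_logits(r[:, :, :, :, 4], obj_target) * self.BALANCE[level]
        total = self.box_w * lbox + self.obj_w * lobj + self.cls_w * lcls
        return total, {
            "box": float(lbox.data) * self.box_w,
            "obj": float(lobj.data) * self.obj_w,
            "cls": float(lcls.data) * self.cls_w,
            "total": float(total.data),
            "n_pos": n_pos,
        }
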