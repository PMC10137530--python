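"""Training loop: Adam on the composed detection loss.

Defaults follow the published recipe: Adam with initial learning rate
0.01, first-moment coefficient 0.937 (the recipe's "momentum"), weight
decay 5e-4, 300 epochs.  Desk-scale runs override epochs/model width; the
loop logs JSON-lines per epoch and checkpoints to ``.npz``.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .data import load_manifest, read_yolo_labels
from .losses import DetectionLoss
from .metrics import evaluate_detections
from .model import Model, decode_predictions
from .tensor import Tensor, no_grad

__all__ = ["Adam", "TrainConfig", "train", "save_checkpoint", "load_checkpoint",
           "evaluate_model"]


class Adam:
    def __init__(self, params, lr=0.01, betas=(0.937, 0.999), eps=1e-8,
                 weight_decay=5e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.wd:
                g = g + self.wd * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class TrainConfig(dict):
    """Plain dict of training options with attribute access."""

    DEFAULTS = dict(
        model="gl_yolo_lite", nc=1, img_size=320, epochs=300, batch_size=8,
        lr=0.01, betas=(0.937, 0.999), weight_decay=5e-4, seed=0,
        width_multiple=None, depth_multiple=None, conf_thres=0.25,
        iou_thres=0.45, anchors=None,
    )

    def __init__(self, **kw):
        super().__init__(self.DEFAULTS)
        unknown = set(kw) - set(self.DEFAULTS) - {"data", "out_dir"}
        if unknown:
            raise ValueError(f"unknown training options: {sorted(unknown)}")
        self.update(kw)

    def __getattr__(self, k):
        try:
            return self[k]
        except KeyError as e:
            raise AttributeError(k) from e


def _load_split(manifest: dict, names, root: Path):
    images, labels = [], []
    size = manifest["image_size"]
    for stem in names:
        img = np.asarray(Image.open(root / "images" / f"{stem}.png").convert("RGB"))
        rows = read_yolo_labels(root / "labels" / f"{stem}.txt")
        images.append(img.transpose(2, 0, 1).astype(np.float32) / 255.0)
        labels.append(rows)
    return np.stack(images), labels, size


def _targets_array(label_list):
    rows = []
    for i, rows_i in enumerate(label_list):
        for cls, cx, cy, w, h in rows_i:
            rows.append((i, cls, cx, cy, w, h))
    return np.asarray(rows, dtype=np.float64).reshape(-1, 6)


def recalibrate_bn(model: Model, images: np.ndarray, batch_size: int = 8,
                   passes: int = 2):
    """Precise-BN pass: re-estimate population statistics under final weights.

    With deep stacks of batch-norm layers the momentum-averaged running
    statistics lag the training distribution, so eval-mode outputs drift
    from train-mode ones.  This replaces the running stats by a cumulative
    average of batch statistics over a few forward passes.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    saved_momentum = [bn.momentum for bn in bns]
    for bn in bns:
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 0.0
    model.train()
    k = 0
    for _ in range(passes):
        for i in range(0, len(images), batch_size):
            k += 1
            for bn in bns:
                bn.momentum = 1.0 / k
            with no_grad():
                model(Tensor(images[i : i + batch_size]))
    for bn, m in zip(bns, saved_momentum):
        bn.momentum = m
    model.eval()
    return model


def save_checkpoint(model: Model, path):
    state = model.state_dict()
    meta = json.dumps(
        {
            "cfg": model.cfg,
            "nc": model.nc,
        }
    )
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **state)


def load_checkpoint(path) -> Model:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = Model(meta["cfg"])
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    return model


def evaluate_model(model: Model, images: np.ndarray, labels, img_size: int,
                   conf_thres=0.25, iou_thres=0.45, batch_size=8):
    """Decode + NMS over a stack of CHW images; returns a MetricsReport."""
    det = model.detect
    model.eval()
    dets_all = []
    for i in range(0, len(images), batch_size):
        with no_grad():
            raw = model(Tensor(images[i : i + batch_size]))
        anchors = [det.anchors[j] for j in range(det.nl)]
        dets_all += decode_predictions(raw, anchors, det.strides,
                                       conf_thres, iou_thres)
    gts = []
    for rows in labels:
        boxes = np.zeros((len(rows), 5))
        for j, (cls, cx, cy, w, h) in enumerate(rows):
            boxes[j] = (
                cls,
                (cx - w / 2) * img_size,
                (cy - h / 2) * img_size,
                (cx + w / 2) * img_size,
                (cy + h / 2) * img_size,
            )
        gts.append(boxes)
    return evaluate_detections(dets_all, gts)


def train(config: TrainConfig, data_dir, out_dir=None, log=print):
    """Train on a generated dataset directory; returns (model, history).

    ``data_dir`` must contain ``manifest.json``, ``images/`` and
    ``labels/`` as written by :func:`glyolite.data.generate_dataset`.
    """
    data_dir = Path(data_dir)
    manifest = load_manifest(data_dir / "manifest.json")
    if not manifest["train"]:
        raise ValueError("empty training split")
    images, labels, img_size = _load_split(manifest, manifest["train"], data_dir)
    if config.img_size != img_size:
        raise ValueError(
            f"config img_size {config.img_size} != dataset size {img_size}"
        )
    cfg = dict(Model(config.model).cfg) if isinstance(config.model, str) else config.model
    if config.anchors is not None:
        cfg = {**cfg, "anchors": config.anchors}
    model = Model(
        cfg, nc=config.nc,
        width_multiple=config.width_multiple, depth_multiple=config.depth_multiple,
        seed=config.seed,
    )
    loss_fn = DetectionLoss(model)
    opt = Adam(model.parameters(), lr=config.lr, betas=tuple(config.betas),
               weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    n = len(images)
    history = []
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    for epoch in range(config.epochs):
        t0 = time.time()
        model.train()
        order = rng.permutation(n)
        comps_sum = {"box": 0.0, "obj": 0.0, "cls": 0.0, "total": 0.0}
        n_batches = 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            batch = Tensor(images[idx])
            targets = _targets_array([labels[j] for j in idx])
            total, comps = loss_fn(model(batch), targets)
            opt.zero_grad()
            total.backward()
            opt.step()
            for k in comps_sum:
                comps_sum[k] += comps[k]
            n_batches += 1
        entry = {
            "epoch": epoch,
            **{k: v / n_batches for k, v in comps_sum.items()},
            "time": round(time.time() - t0, 2),
        }
        history.append(entry)
        if log:
            log(f"epoch {epoch:3d}  " + "  ".join(
                f"{k}={entry[k]:.4f}" for k in ("box", "obj", "cls", "total")
            ))
        if out_dir:
            with open(out_dir / "log.jsonl", "a") as fh:
                fh.write(json.dumps(entry) + "\n")
    recalibrate_bn(model, images, config.batch_size)
    if out_dir:
        save_checkpoint(model, out_dir / "checkpoint.npz")
    return model, history
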