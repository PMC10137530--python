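"""Declarative model assembly: the whole network is data, not code.

A model is a YAML layer table (mirroring the published architecture tables)
with rows ``[from, number, module, args]``.  ``build_from_table`` turns the
table into a runnable graph; shipped tables cover the YOLOv5s baseline,
GL-YOLO, its stem-entry ablation variant, and GL-YOLO-Lite.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import yaml

from . import blocks, nn
from .tensor import Tensor, no_grad

__all__ = [
    "ConfigError", "Model", "build_from_table", "load_config", "config_path",
    "letterbox", "decode_predictions", "nms", "detect_image", "make_divisible",
]


class ConfigError(ValueError):
    pass


_REGISTRY = {
    "focus": blocks.Focus,
    "stem": blocks.Stem,
    "stemblock": blocks.Stem,
    "conv": blocks.ConvUnit,
    "rep": blocks.RepConv,
    "repblock": blocks.RepConv,
    "c3": blocks.C3,
    "cot3": blocks.CoT3,
    "spp": blocks.SPP,
    "simam": blocks.SimAM,
    "concat": blocks.Concat,
    "upsample": blocks.Upsample,
    "up-sample": blocks.Upsample,
    "detect": blocks.Detect,
}


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(int(round(x / divisor) * divisor), divisor)


def config_path(name: str) -> Path:
    """Path of a shipped architecture table (``yolov5s``, ``gl_yolo``, ...)."""
    base = importlib.resources.files("glyolite") / "configs"
    p = Path(str(base / f"{name}.yaml"))
    if not p.exists():
        raise ConfigError(f"no shipped config named {name!r}")
    return p


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    p = Path(source)
    if not p.exists():
        p = config_path(str(source))
    with open(p) as fh:
        return yaml.safe_load(fh)


class Model(nn.Module):
    """A detection network built from a layer table.

    Parameters
    ----------
    cfg : dict | str | Path
        Parsed config, path to a YAML file, or a shipped config name.
    nc : int, optional
        Override the table's class count.
    width_multiple, depth_multiple : float, optional
        Override the table's scaling multiples (used for small test models).
    seed : int
        Seed for weight initialisation.
    """

    def __init__(self, cfg, nc=None, width_multiple=None, depth_multiple=None,
                 seed: int = 0):
        super().__init__()
        cfg = load_config(cfg)
        if nc is not None:
            cfg["nc"] = int(nc)
        if width_multiple is not None:
            cfg["width_multiple"] = float(width_multiple)
        if depth_multiple is not None:
            cfg["depth_multiple"] = float(depth_multiple)
        self.cfg = cfg
        self.nc = int(cfg["nc"])
        rng = np.random.default_rng(seed)
        self.layers, self._froms, self.saves = _parse(cfg, rng)
        self._has_detect = isinstance(self.layers[-1], blocks.Detect)
        if self.detect is not None:
            shapes = self.layer_shapes(256)
            strides = [256 // shapes[i][1] for i in self.layers_from[-1]]
            order = np.argsort(strides)
            if not np.all(order == np.arange(len(strides))):
                raise ConfigError("detect inputs must be ordered fine-to-coarse")
            # anchors sorted by area ascending, grouped 3 per scale
            flat = self.detect.anchors.reshape(-1, 2)
            flat = flat[np.argsort(flat[:, 0] * flat[:, 1])]
            self.detect.anchors = flat.reshape(self.detect.nl, self.detect.na, 2)
            self.detect.initialize_biases(strides)

    # ----------------------------------------------------------------- build
    @property
    def detect(self):
        return self.layers[-1] if self._has_detect else None

    @property
    def layers_from(self):
        return self._froms

    def forward(self, x: Tensor):
        y = {}
        out = x
        for i, (m, f) in enumerate(zip(self.layers, self._froms)):
            if len(f) == 1:
                inp = out if f[0] == -1 else y[f[0]]
                out = m(inp)
            else:
                out = m([out if j == -1 else y[j] for j in f])
            if i in self.saves:
                y[i] = out
        return out

    def layer_shapes(self, img_size: int):
        """Analytic (C, H, W) after every layer for a square input."""
        shapes = []
        cur = (3, img_size, img_size)
        for i, (m, f) in enumerate(zip(self.layers, self._froms)):
            if isinstance(m, (blocks.Concat, blocks.Detect)):
                ins = [cur if j == -1 else shapes[j] for j in f]
                _, c, h, w = m.profile(ins)
            else:
                c_in, h_in, w_in = cur if f[0] == -1 else shapes[f[0]]
                _, c, h, w = m.profile(c_in, h_in, w_in)
            cur = (c, h, w)
            shapes.append(cur)
        return shapes

    def to_deploy(self):
        from .reparam import convert_model_to_deploy

        return convert_model_to_deploy(self)


def _parse(cfg: dict, rng):
    rows = list(cfg.get("backbone", [])) + list(cfg.get("head", []))
    if not rows:
        raise ConfigError("empty layer table")
    gd = float(cfg.get("depth_multiple", 1.0))
    gw = float(cfg.get("width_multiple", 1.0))
    nc = int(cfg["nc"])
    anchors = cfg["anchors"]
    ch = [3]
    layers, froms, saves = [], [], set()
    for i, row in enumerate(rows):
        f, n, name, args = row
        f = [f] if isinstance(f, int) else list(f)
        for j in f:
            if j != -1 and not (0 <= j < i):
                raise ConfigError(f"layer {i}: input ref {j} out of range")
        key = str(name).lower()
        if key not in _REGISTRY:
            raise ConfigError(f"layer {i}: unknown module {name!r}")
        cls = _REGISTRY[key]
        n_rep = max(round(n * gd), 1) if n > 1 else n
        c1 = ch[(f[0] + 1) if f[0] != -1 else i]  # ch[0] is the image

        def width(c):
            return make_divisible(c * gw)

        if cls in (blocks.Focus, blocks.Stem):
            c2 = width(args[0])
            m = cls(c1, c2, *args[1:], rng=rng)
        elif cls is blocks.ConvUnit:
            c2 = width(args[0])
            m = cls(c1, c2, *args[1:], rng=rng)
        elif cls is blocks.RepConv:
            c2 = width(args[0])
            k = args[1] if len(args) > 1 else 3
            s = args[2] if len(args) > 2 else 1
            m = cls(c1, c2, k, s, rng=rng)
        elif cls in (blocks.C3, blocks.CoT3):
            c2 = width(args[0])
            shortcut = bool(args[1]) if len(args) > 1 else True
            m = cls(c1, c2, n_rep, shortcut, rng=rng)
        elif cls is blocks.SPP:
            c2 = width(args[0])
            m = cls(c1, c2, tuple(args[1]), rng=rng)
        elif cls is blocks.SimAM:
            c2 = c1
            m = cls(*args[1:])
        elif cls is blocks.Concat:
            c2 = sum(ch[(j + 1) if j != -1 else i] for j in f)
            m = cls(*args)
        elif cls is blocks.Upsample:
            c2 = c1
            m = cls(*args)
        elif cls is blocks.Detect:
            in_ch = [ch[j + 1] for j in f]
            m = cls(nc, anchors, in_ch, rng=rng)
            c2 = m.no * m.na
        layers.append(m)
        froms.append(f)
        saves.update(j for j in f if j != -1)
        ch.append(c2)
    return layers, froms, saves


def build_from_table(cfg, **kwargs) -> Model:
    """Build a runnable model from a layer table (see :class:`Model`)."""
    return Model(cfg, **kwargs)


# --------------------------------------------------------------------------
# letterboxing and detection decode
# --------------------------------------------------------------------------

def letterbox(img: np.ndarray, size: int = 640, color: int = 114):
    """Aspect-preserving resize with gray padding to ``size`` x ``size``.

    Returns ``(canvas, scale, (pad_x, pad_y))``; ``canvas`` is HWC uint8.
    """
    from PIL import Image

    h, w = img.shape[:2]
    scale = min(size / h, size / w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = np.asarray(
        Image.fromarray(img).resize((nw, nh), Image.BILINEAR)
    )
    canvas = np.full((size, size, img.shape[2]), color, dtype=np.uint8)
    px, py = (size - nw) // 2, (size - nh) // 2
    canvas[py : py + nh, px : px + nw] = resized
    return canvas, scale, (px, py)


def _iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """IoU between two (N,4) / (M,4) arrays of xyxy boxes."""
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    return inter / np.clip(area_a[:, None] + area_b[None, :] - inter, 1e-9, None)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thres: float = 0.45):
    """Greedy non-maximum suppression; returns kept indices."""
    order = np.argsort(-scores)
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        ious = _iou_matrix(boxes[i : i + 1], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_thres]
    return np.asarray(keep, dtype=int)


def decode_predictions(raw, anchors, strides, conf_thres=0.25, iou_thres=0.45):
    """Decode raw head outputs into pixel boxes with per-class NMS.

    ``raw``: list of (N, na, H, W, 5+nc) arrays (or tensors), one per scale.
    Grid decode: xy = (2*sig(t) - 0.5 + grid) * stride,
    wh = (2*sig(t))^2 * anchor; confidence = sig(obj) * sig(cls).
    """
    results = []
    batch = raw[0].shape[0]
    for n in range(batch):
        rows = []
        for level, r in enumerate(raw):
            arr = r.data if isinstance(r, Tensor) else np.asarray(r)
            na, h, w = arr.shape[1], arr.shape[2], arr.shape[3]
            p = 1.0 / (1.0 + np.exp(-arr[n]))
            gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            xy = (2 * p[..., :2] - 0.5 + np.stack([gx, gy], -1)) * strides[level]
            wh = (2 * p[..., 2:4]) ** 2 * anchors[level][:, None, None, :]
            obj = p[..., 4]
            cls = p[..., 5:]
            conf = obj[..., None] * cls
            best = conf.max(-1)
            mask = best > conf_thres
            if not mask.any():
                continue
            xy, wh = xy[mask], wh[mask]
            cls_id = conf[mask].argmax(-1)
            score = best[mask]
            xyxy = np.concatenate([xy - wh / 2, xy + wh / 2], axis=-1)
            rows.append(
                np.concatenate(
                    [xyxy, score[:, None], cls_id[:, None].astype(np.float32)], axis=1
                )
            )
        if not rows:
            results.append(np.zeros((0, 6), dtype=np.float32))
            continue
        dets = np.concatenate(rows, 0)
        kept = []
        for c in np.unique(dets[:, 5]):
            sub = dets[dets[:, 5] == c]
            idx = nms(sub[:, :4], sub[:, 4], iou_thres)
            kept.append(sub[idx])
        dets = np.concatenate(kept, 0)
        results.append(dets[np.argsort(-dets[:, 4])])
    return results


def detect_image(model: Model, image: np.ndarray, img_size: int = 640,
                 conf_thres: float = 0.25, iou_thres: float = 0.45):
    """Run the detector on one HWC uint8 RGB image.

    Returns an (N, 6) array of (x1, y1, x2, y2, score, class) in the
    original image frame (0-based half-open pixel boxes).
    """
    if model.detect is None or model.detect.strides is None:
        raise ConfigError("model has no configured detection head/anchors")
    canvas, scale, (px, py) = letterbox(image, img_size)
    x = Tensor(canvas.transpose(2, 0, 1)[None].astype(np.float32) / 255.0)
    model.eval()
    with no_grad():
        raw = model(x)
    det = model.detect
    scaled_anchors = [det.anchors[i] for i in range(det.nl)]
    out = decode_predictions(raw, scaled_anchors, det.strides, conf_thres, iou_thres)[0]
    if len(out):
        out = out.copy()
        out[:, [0, 2]] = (out[:, [0, 2]] - px) / scale
        out[:, [1, 3]] = (out[:, [1, 3]] - py) / scale
    return out
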