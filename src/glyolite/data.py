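"""Synthetic detection fixtures and label-format I/O.

The generator emulates the structure of a single-class fallen-person
dataset: photographic clutter is replaced by textured backgrounds, and the
"fall" targets by high-contrast filled shapes (rotated rectangles and
ellipses) with orientation jitter — enough signal for a small detector to
learn localisation without any human-subject imagery.  Labels are written
in YOLO txt format (``class cx cy w h``, normalised), and datasets are
split 80/16/4 into train/test/val.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

__all__ = [
    "DatasetSplit", "generate_dataset", "generate_scene",
    "read_yolo_labels", "write_yolo_labels", "yolo_to_xyxy", "xyxy_to_yolo",
    "read_voc_xml", "write_voc_xml", "load_manifest",
]

SPLIT_RATIOS = (0.80, 0.16, 0.04)


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    test: list = field(default_factory=list)
    val: list = field(default_factory=list)
    ratios: tuple = SPLIT_RATIOS

    def manifest(self) -> dict:
        return {
            "train": [str(p) for p in self.train],
            "test": [str(p) for p in self.test],
            "val": [str(p) for p in self.val],
            "ratios": list(self.ratios),
        }


def split_files(files, ratios=SPLIT_RATIOS, seed: int = 0) -> DatasetSplit:
    """Deterministic disjoint, exhaustive split; sizes within one file of
    the exact ratios (train gets the remainder)."""
    files = list(files)
    order = np.random.default_rng(seed).permutation(len(files))
    n = len(files)
    n_test = int(round(n * ratios[1]))
    n_val = int(round(n * ratios[2]))
    n_train = n - n_test - n_val
    shuffled = [files[i] for i in order]
    return DatasetSplit(
        shuffled[:n_train],
        shuffled[n_train : n_train + n_test],
        shuffled[n_train + n_test :],
        ratios,
    )


# ---------------------------------------------------------------- scenes

def _textured_background(rng, size: int) -> np.ndarray:
    """Low-frequency noise texture in a random muted colour range."""
    coarse = rng.uniform(0, 1, (8, 8, 3))
    img = np.asarray(
        Image.fromarray((coarse * 255).astype(np.uint8)).resize(
            (size, size), Image.BILINEAR
        ),
        dtype=np.float32,
    )
    base = rng.uniform(30, 110, 3).astype(np.float32)
    out = base + (img - 127.5) * rng.uniform(0.15, 0.35)
    out += rng.normal(0, 6, out.shape)
    return np.clip(out, 0, 255).astype(np.uint8)


def generate_scene(seed: int, image_size: int = 320, boxes_per_image: int = 1):
    """One synthetic scene: textured background + bright shape targets.

    Returns ``(image HWC uint8, labels (n, 5) of class cx cy w h)``.
    """
    rng = np.random.default_rng(seed)
    img = _textured_background(rng, image_size)
    pil = Image.fromarray(img)
    draw = ImageDraw.Draw(pil)
    labels = []
    for _ in range(boxes_per_image):
        w = rng.uniform(0.18, 0.45) * image_size
        h = rng.uniform(0.18, 0.45) * image_size
        cx = rng.uniform(w / 2 + 2, image_size - w / 2 - 2)
        cy = rng.uniform(h / 2 + 2, image_size - h / 2 - 2)
        color = tuple(int(c) for c in rng.uniform(180, 255, 3))
        theta = rng.uniform(0, np.pi)
        if rng.random() < 0.5:
            # rotated filled rectangle (an elongated "fallen" bar)
            ax, ay = np.cos(theta), np.sin(theta)
            bx, by = -ay, ax
            hw, hh = w * 0.5, h * 0.22
            pts = [
                (cx + sx * hw * ax + sy * hh * bx, cy + sx * hw * ay + sy * hh * by)
                for sx, sy in [(-1, -1), (1, -1), (1, 1), (-1, 1)]
            ]
            draw.polygon(pts, fill=color)
            xs = [p[0] for p in pts]
            ys = [p[1] for p in pts]
        else:
            x1, y1 = cx - w / 2, cy - h / 2
            x2, y2 = cx + w / 2, cy + h / 2
            draw.ellipse([x1, y1, x2, y2], fill=color)
            xs, ys = [x1, x2], [y1, y2]
        x1 = max(min(xs), 0.0)
        y1 = max(min(ys), 0.0)
        x2 = min(max(xs), float(image_size))
        y2 = min(max(ys), float(image_size))
        labels.append(xyxy_to_yolo((x1, y1, x2, y2), image_size, cls=0))
    arr = np.asarray(pil)
    return arr, np.asarray(labels, dtype=np.float64).reshape(-1, 5)


def generate_dataset(n_images: int, out_dir, image_size: int = 320,
                     boxes_per_image: int = 1, seed: int = 0) -> DatasetSplit:
    """Write a synthetic dataset (images/ + labels/) and its split manifest."""
    if n_images < 5:
        raise ValueError("need at least 5 images for a non-empty val split")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    stems = []
    for i in range(n_images):
        img, labels = generate_scene(seed * 1_000_003 + i, image_size, boxes_per_image)
        stem = f"img_{i:05d}"
        Image.fromarray(img).save(out_dir / "images" / f"{stem}.png")
        write_yolo_labels(labels, out_dir / "labels" / f"{stem}.txt")
        stems.append(stem)
    split = split_files(stems, seed=seed)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(
            {**split.manifest(), "image_size": image_size, "seed": seed}, fh, indent=1
        )
    return split


def load_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ------------------------------------------------------------- YOLO labels

def read_yolo_labels(path) -> np.ndarray:
    """Read a YOLO txt label file into an (n, 5) array (class, cx, cy, w, h)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from e
            if vals[0] != int(vals[0]) or vals[0] < 0:
                raise ValueError(f"{path}:{lineno}: bad class id {parts[0]}")
            if not all(0.0 <= v <= 1.0 for v in vals[1:]):
                raise ValueError(f"{path}:{lineno}: coordinate out of [0, 1]")
            rows.append(vals)
    return np.asarray(rows, dtype=np.float64).reshape(-1, 5)


def write_yolo_labels(labels, path):
    labels = np.asarray(labels, dtype=np.float64).reshape(-1, 5)
    with open(path, "w") as fh:
        for cls, cx, cy, w, h in labels:
            fh.write(f"{int(cls)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n")


def yolo_to_xyxy(row, image_size: int) -> tuple:
    """Normalised centre box -> 0-based half-open pixel corners."""
    _, cx, cy, w, h = row
    return (
        (cx - w / 2) * image_size,
        (cy - h / 2) * image_size,
        (cx + w / 2) * image_size,
        (cy + h / 2) * image_size,
    )


def xyxy_to_yolo(box, image_size: int, cls: int = 0):
    x1, y1, x2, y2 = box
    return (
        cls,
        (x1 + x2) / 2 / image_size,
        (y1 + y2) / 2 / image_size,
        (x2 - x1) / image_size,
        (y2 - y1) / image_size,
    )


# ---------------------------------------------------------------- VOC XML

def read_voc_xml(path):
    """Parse a Pascal-VOC XML file.

    VOC boxes are 1-based inclusive pixel coordinates; they are converted
    to the internal 0-based half-open convention (xmin-1, ymin-1, xmax, ymax).
    Returns ``(boxes (n, 4), names list)``.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    boxes, names = [], []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"{path}: object without bndbox")
        vals = {}
        for key in ("xmin", "ymin", "xmax", "ymax"):
            txt = bnd.findtext(key)
            if txt is None:
                raise ValueError(f"{path}: bndbox missing {key}")
            vals[key] = float(txt)
        boxes.append(
            (vals["xmin"] - 1, vals["ymin"] - 1, vals["xmax"], vals["ymax"])
        )
        names.append(name)
    return np.asarray(boxes, dtype=np.float64).reshape(-1, 4), names


def write_voc_xml(path, boxes, names, image_size=(640, 640)):
    """Inverse of :func:`read_voc_xml` (internal convention in, VOC out)."""
    import xml.etree.ElementTree as ET

    root = ET.Element("annotation")
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(image_size[0])
    ET.SubElement(size, "height").text = str(image_size[1])
    for (x1, y1, x2, y2), name in zip(boxes, names):
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = str(name)
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(int(round(x1 + 1)))
        ET.SubElement(bnd, "ymin").text = str(int(round(y1 + 1)))
        ET.SubElement(bnd, "xmax").text = str(int(round(x2)))
        ET.SubElement(bnd, "ymax").text = str(int(round(y2)))
    ET.ElementTree(root).write(path)
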