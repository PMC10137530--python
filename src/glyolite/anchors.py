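"""K-means++ anchor generation from labelled box dimensions.

Anchors are clustered on absolute (width, height) pairs at the network
input scale with plain Euclidean distance — k-means++ seeding (D-squared
sampling) followed by Lloyd iterations.  The nine resulting centres are
sorted by area and grouped three per detection scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AnchorSet", "kmeanspp_seed", "cluster_anchors", "load_label_boxes"]


@dataclass
class AnchorSet:
    anchors: np.ndarray            # (k, 2) float, sorted ascending by area
    inertia: float
    seed: int
    n_iter: int
    inertia_history: list = field(default_factory=list)

    @property
    def scales(self):
        """Anchor triples grouped per detection scale, small to large."""
        k = len(self.anchors)
        per = k // 3 if k % 3 == 0 else k
        return [self.anchors[i : i + per] for i in range(0, k, per)]

    def as_config_list(self):
        return [np.round(s.reshape(-1), 0).astype(int).tolist() for s in self.scales]


def _check_boxes(boxes) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 2)
    if len(boxes) == 0 or np.any(boxes <= 0):
        raise ValueError("boxes must be positive (w, h) pairs")
    return boxes


def kmeanspp_seed(boxes, k: int, seed: int = 0) -> np.ndarray:
    """D-squared seeding: each next centre is sampled with probability
    proportional to its squared distance to the nearest chosen centre."""
    boxes = _check_boxes(boxes)
    distinct = np.unique(boxes, axis=0)
    if k > len(distinct):
        raise ValueError(f"k={k} exceeds {len(distinct)} distinct boxes")
    rng = np.random.default_rng(seed)
    centers = np.empty((k, 2), dtype=np.float64)
    centers[0] = boxes[rng.integers(len(boxes))]
    d2 = ((boxes - centers[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        probs = d2 / d2.sum()
        centers[i] = boxes[rng.choice(len(boxes), p=probs)]
        d2 = np.minimum(d2, ((boxes - centers[i]) ** 2).sum(axis=1))
    return centers


def _inertia(boxes, centers):
    d2 = ((boxes[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum()), d2.argmin(axis=1)


def cluster_anchors(boxes, k: int = 9, seed: int = 0, max_iter: int = 300,
                    tol: float = 1e-6) -> AnchorSet:
    """Lloyd's algorithm from a k-means++ seeding on (w, h) space."""
    boxes = _check_boxes(boxes)
    if len(np.unique(boxes, axis=0)) == 1 and k > 1:
        raise ValueError("all boxes identical; cannot form k > 1 clusters")
    centers = kmeanspp_seed(boxes, k, seed)
    history = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        inertia, assign = _inertia(boxes, centers)
        history.append(inertia)
        new_centers = centers.copy()
        for j in range(k):
            members = boxes[assign == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    inertia, _ = _inertia(boxes, centers)
    history.append(inertia)
    order = np.argsort(centers[:, 0] * centers[:, 1])
    return AnchorSet(centers[order], inertia, seed, n_iter, history)


def load_label_boxes(labels_dir, img_size: int = 640) -> np.ndarray:
    """Collect (w, h) pairs in input pixels from a directory of YOLO-txt labels.

    Normalised label dimensions are multiplied by the configured input size;
    empty label files are skipped.
    """
    from .data import read_yolo_labels

    out = []
    for path in sorted(Path(labels_dir).glob("*.txt")):
        rows = read_yolo_labels(path)
        if len(rows):
            out.append(rows[:, 3:5] * img_size)
    if not out:
        raise ValueError(f"no labelled boxes found under {labels_dir}")
    return np.concatenate(out, axis=0)
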