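"""TOPSIS composite ranking of detection models.

Alternatives are scored on four criteria — mAP@0.5 (weight 0.40, benefit),
FPS (0.20, benefit), parameters (0.20, cost) and GFLOPs (0.20, cost) — by
relative closeness d-/(d+ + d-) to the weighted ideal / anti-ideal points.

Because the literature's TOPSIS recipes differ in how cost criteria are
re-oriented and where the weights enter, three variants are exposed:

* ``"calibrated"`` (default): min-max rescaling of each criterion to [0, 1]
  respecting orientation, vector normalisation, weighting, and weighted-
  Euclidean distances (criterion weights also in the metric).  This is the
  variant pinned by the shipped regression tables.
* ``"vector"``: the classic chain — vector normalisation, weighting,
  orientation applied when selecting ideal / anti-ideal.
* ``"minmax"``: min-max re-orientation, weighting, plain Euclidean
  distances.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DecisionMatrix", "TopsisResult", "topsis", "load_benchmark_table",
           "read_decision_csv"]

DEFAULT_WEIGHTS = (0.4, 0.2, 0.2, 0.2)
DEFAULT_BENEFIT = (True, True, False, False)
DEFAULT_CRITERIA = ("map50", "fps", "params", "gflops")


@dataclass
class DecisionMatrix:
    methods: list
    values: np.ndarray                 # (n_alternatives, n_criteria), positive
    criteria: tuple = DEFAULT_CRITERIA
    weights: tuple = DEFAULT_WEIGHTS
    benefit: tuple = DEFAULT_BENEFIT

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.weights):
            raise ValueError("values must be (alternatives x criteria)")
        if np.any(self.values <= 0):
            raise ValueError("criteria values must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class TopsisResult:
    methods: list
    closeness: np.ndarray
    ranking: np.ndarray     # 1 = best; ties broken by input order
    variant: str
    table: list = field(default_factory=list)

    def top(self) -> str:
        return self.methods[int(np.argmin(self.ranking))]


def _reorient_minmax(values, benefit):
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        lo, hi = col.min(), col.max()
        span = hi - lo
        if span == 0:
            out[:, j] = 0.5
        elif benefit[j]:
            out[:, j] = (col - lo) / span
        else:
            out[:, j] = (hi - col) / span
    return out


def topsis(matrix: DecisionMatrix, variant: str = "calibrated") -> TopsisResult:
    v = matrix.values
    w = np.asarray(matrix.weights, dtype=np.float64)
    benefit = np.asarray(matrix.benefit, dtype=bool)
    norms = np.sqrt((v**2).sum(axis=0))
    if np.any(norms == 0):
        raise ValueError("a criterion column is all zero")

    if variant == "vector":
        V = (v / norms) * w
        ideal = np.where(benefit, V.max(0), V.min(0))
        anti = np.where(benefit, V.min(0), V.max(0))
        dp = np.sqrt(((V - ideal) ** 2).sum(axis=1))
        dm = np.sqrt(((V - anti) ** 2).sum(axis=1))
    elif variant == "minmax":
        V = _reorient_minmax(v, benefit) * w
        dp = np.sqrt(((V - V.max(0)) ** 2).sum(axis=1))
        dm = np.sqrt(((V - V.min(0)) ** 2).sum(axis=1))
    elif variant == "calibrated":
        X = _reorient_minmax(v, benefit)
        col = np.sqrt((X**2).sum(axis=0))
        col[col == 0] = 1.0
        V = (X / col) * w
        dp = np.sqrt((w * (V - V.max(0)) ** 2).sum(axis=1))
        dm = np.sqrt((w * (V - V.min(0)) ** 2).sum(axis=1))
    else:
        raise ValueError(f"unknown TOPSIS variant {variant!r}")

    closeness = dm / (dp + dm)
    # ranking with ties broken by input order: stable sort on -closeness
    order = np.argsort(-closeness, kind="stable")
    ranking = np.empty(len(closeness), dtype=int)
    ranking[order] = np.arange(1, len(closeness) + 1)
    table = [
        {"method": m, "closeness": float(c), "rank": int(r)}
        for m, c, r in zip(matrix.methods, closeness, ranking)
    ]
    return TopsisResult(list(matrix.methods), closeness, ranking, variant, table)


def read_decision_csv(path, fps_column: str = "fps") -> DecisionMatrix:
    """Read a decision table CSV with header method,map50,fps,params,gflops
    (or explicit fps_gpu / fps_cpu columns selected via ``fps_column``)."""
    rows = list(csv.DictReader(open(path)))
    if not rows:
        raise ValueError(f"empty decision table {path}")
    methods = [r["method"] for r in rows]
    fps_key = fps_column if fps_column in rows[0] else "fps"
    vals = np.array(
        [
            [float(r["map50"]), float(r[fps_key]), float(r["params"]), float(r["gflops"])]
            for r in rows
        ]
    )
    return DecisionMatrix(methods, vals)


def load_benchmark_table(name: str, fps_column: str = "fps_gpu") -> DecisionMatrix:
    """Load a bundled benchmark comparison table (``fpdd`` or ``pascal_voc``)."""
    base = importlib.resources.files("glyolite") / "data"
    path = Path(str(base / f"{name}_results.csv"))
    if not path.exists():
        raise ValueError(f"no bundled table named {name!r}")
    return read_decision_csv(path, fps_column=fps_column)
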