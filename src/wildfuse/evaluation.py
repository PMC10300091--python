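"""Detection-evaluation statistics and mAP50 rank aggregation.

Covers IoU box matching, precision/recall, average precision at a 50% IoU
threshold (101-point interpolation), relative-improvement percentages, and
the dense-rank aggregation used to compare fusion methods across species and
detector architectures. A published per-(species, architecture, method)
mAP50 grid for cow/deer/horse surveys ships with the package and can be
loaded with :func:`load_published_map50_grid`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, BoundingBox

FUSION_METHODS = (
    "guided_filter",
    "laplacian",
    "svd",
    "sparse",
    "gradient",
    "tvm",
    "wl_tvm",
    "wl_swarm",
)
#: the two unfused baselines plus the eight fusion methods
ALL_METHODS = ("visible", "thermal") + FUSION_METHODS


class UndefinedMetric(ValueError):
    """A ratio metric whose denominator is zero; reported as absent, not 0."""


@dataclass
class MatchResult:
    """Outcome of matching predicted boxes to ground truth for all classes."""

    true_positives: int
    false_positives: int
    false_negatives: int
    pairings: list[tuple[int, int, float]] = field(default_factory=list)
    """(prediction index, truth index, IoU) per matched pair."""


def iou(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Intersection-over-union of two half-open axis-aligned boxes."""
    ix = min(box_a.x_max, box_b.x_max) - max(box_a.x_min, box_b.x_min)
    iy = min(box_a.y_max, box_b.y_max) - max(box_a.y_min, box_b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (box_a.area + box_b.area - inter)


def _confidence_order(preds: Sequence[BoundingBox]) -> list[int]:
    # descending confidence; missing confidence sorts last; index breaks ties
    return sorted(
        range(len(preds)),
        key=lambda i: (-(preds[i].confidence if preds[i].confidence is not None else 0.0), i),
    )


def match_detections(
    predictions: AnnotationSet | Sequence[BoundingBox],
    truths: AnnotationSet | Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> MatchResult:
    """Greedy confidence-ordered matching within each class.

    Each prediction, in descending confidence order, is paired with the
    still-unmatched same-class truth box of highest IoU provided that IoU
    reaches the threshold. Unmatched predictions count as false positives,
    unmatched truths as false negatives; a truth box is matched at most once.
    """
    preds = list(predictions)
    gts = list(truths)
    matched_truth: set[int] = set()
    pairings: list[tuple[int, int, float]] = []
    for pi in _confidence_order(preds):
        p = preds[pi]
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(gts):
            if j in matched_truth or t.class_label != p.class_label:
                continue
            v = iou(p, t)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched_truth.add(best_j)
            pairings.append((pi, best_j, best_iou))
    tp = len(pairings)
    return MatchResult(
        true_positives=tp,
        false_positives=len(preds) - tp,
        false_negatives=len(gts) - tp,
        pairings=pairings,
    )


def precision(match: MatchResult) -> float:
    """TP / (TP + FP); raises :class:`UndefinedMetric` when no predictions."""
    denom = match.true_positives + match.false_positives
    if denom == 0:
        raise UndefinedMetric("precision undefined: no predictions")
    return match.true_positives / denom


def recall(match: MatchResult) -> float:
    """TP / (TP + FN); raises :class:`UndefinedMetric` when no truth boxes."""
    denom = match.true_positives + match.false_negatives
    if denom == 0:
        raise UndefinedMetric("recall undefined: no ground-truth objects")
    return match.true_positives / denom


def average_precision(
    predictions: AnnotationSet | Sequence[BoundingBox],
    truths: AnnotationSet | Sequence[BoundingBox],
    class_label: str,
    iou_threshold: float = 0.5,
    interpolation: str = "101point",
) -> float:
    """AP for one class from a confidence-swept precision–recall curve."""
    gts = [t for t in truths if t.class_label == class_label]
    preds = [p for p in predictions if p.class_label == class_label]
    if not gts:
        raise UndefinedMetric(f"no ground truth of class {class_label!r}")
    if not preds:
        return 0.0
    order = _confidence_order(preds)
    matched: set[int] = set()
    tp_flags = np.zeros(len(preds), dtype=bool)
    for rank, pi in enumerate(order):
        p = preds[pi]
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(gts):
            if j in matched:
                continue
            v = iou(p, t)
            if v >= iou_threshold and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched.add(best_j)
            tp_flags[rank] = True
    tp_cum = np.cumsum(tp_flags)
    n_pred = np.arange(1, len(preds) + 1)
    prec = tp_cum / n_pred
    rec = tp_cum / len(gts)
    if interpolation == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        ap = 0.0
        for r in grid:
            mask = rec >= r - 1e-12
            ap += prec[mask].max() if mask.any() else 0.0
        return ap / 101.0
    if interpolation == "all_points":
        # envelope precision, integrate over recall steps
        env = np.maximum.accumulate(prec[::-1])[::-1]
        r_prev = 0.0
        ap = 0.0
        for k in range(len(rec)):
            ap += env[k] * (rec[k] - r_prev)
            r_prev = rec[k]
        return ap
    raise ValueError(f"unknown interpolation: {interpolation!r}")


def map50(
    predictions: AnnotationSet | Sequence[BoundingBox],
    truths: AnnotationSet | Sequence[BoundingBox],
    iou_threshold: float = 0.5,
    interpolation: str = "101point",
) -> float:
    """Unweighted mean AP over the classes present in the ground truth."""
    labels = sorted({t.class_label for t in truths})
    if not labels:
        raise UndefinedMetric("no ground-truth objects")
    aps = [
        average_precision(predictions, truths, lab, iou_threshold, interpolation)
        for lab in labels
    ]
    return float(np.mean(aps))


def relative_improvement(value: float, baseline: float) -> int:
    """Signed integer percent change, rounded half away from zero."""
    if baseline <= 0:
        raise UndefinedMetric("relative improvement undefined for non-positive baseline")
    pct = (value / baseline - 1.0) * 100.0
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct)) if pct else 0


# ---------------------------------------------------------------------------
# Rank aggregation over the (species x architecture) mAP50 grid
# ---------------------------------------------------------------------------


@dataclass
class EvalTable:
    """mAP50 grid indexed by (species, architecture, method) with optional
    dense ranks per column and summed rank scores per method."""

    grid: pd.DataFrame  # columns: species, architecture, method, map50
    ranks: pd.DataFrame | None = None  # + rank column
    rank_scores: pd.Series | None = None  # method -> summed rank, ascending

    @classmethod
    def from_csv(cls, path: str | Path) -> "EvalTable":
        df = pd.read_csv(path)
        missing = {"species", "architecture", "method", "map50"} - set(df.columns)
        if missing:
            raise ValueError(f"grid CSV missing columns: {sorted(missing)}")
        return cls(grid=df)

    def to_csv(self, path: str | Path) -> None:
        out = self.ranks if self.ranks is not None else self.grid
        if self.rank_scores is not None:
            out = out.merge(
                self.rank_scores.rename("rank_score"), left_on="method", right_index=True
            )
        out.to_csv(path, index=False)


def load_published_map50_grid() -> EvalTable:
    """The packaged cow/deer/horse x YOLOv5/YOLOv7 mAP50 grid (printed input)."""
    with resources.files("wildfuse.data").joinpath("map50_grid.csv").open() as fh:
        return EvalTable(grid=pd.read_csv(fh))


def dense_rank_scores(table: EvalTable) -> EvalTable:
    """Dense-rank each (species, architecture) column on mAP50, descending.

    Tied values share a rank and the next distinct value gets the next
    consecutive integer. The rank score of a method is the sum of its ranks
    over all columns; the returned scores are sorted ascending (best first).
    """
    df = table.grid.copy()
    cols = df.groupby(["species", "architecture"])
    n_methods = df["method"].nunique()
    for _, sub in cols:
        if sub["method"].nunique() != n_methods:
            raise ValueError("every method must appear in every (species, architecture) column")
    df["rank"] = (
        cols["map50"].rank(method="dense", ascending=False).astype(int)
    )
    scores = df.groupby("method")["rank"].sum().sort_values(kind="stable").rename("rank_score")
    return EvalTable(grid=table.grid, ranks=df, rank_scores=scores)
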