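"""Detection and segmentation metrics.

Detections (boxes or per-object masks) are matched one-to-one against
ground truth at a 70% overlap criterion; precision, recall, F1 and the
area under the precision-recall curve (AP) summarize detection quality.
Segmentations are scored with the Jaccard index and its k-pixel-dilated
variant, which tolerates annotation error near the thin cleft boundary by
dilating both prediction and truth by k pixels before intersecting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stack_io import DetectionBox


@dataclass
class MatchResult:
    """One-to-one matching outcome between predictions and ground truths."""

    true_positives: int
    false_positives: int
    false_negatives: int
    pairs: list[tuple[int, int]] = field(default_factory=list)  # (pred, truth)

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 1.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 1.0


@dataclass
class PRCurve:
    """Precision-recall points swept over the prediction score threshold."""

    recalls: np.ndarray
    precisions: np.ndarray
    thresholds: np.ndarray


def _box_overlap(a: DetectionBox, b: DetectionBox, kind: str) -> float:
    ix = max(0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    if kind == "iot":
        return inter / b.area if b.area else 0.0
    union = a.area + b.area - inter
    return inter / union if union else 0.0


def _mask_overlap(a: np.ndarray, b: np.ndarray, kind: str) -> float:
    inter = int(np.logical_and(a, b).sum())
    if kind == "iot":
        tot = int(np.count_nonzero(b))
        return inter / tot if tot else 0.0
    union = int(np.logical_or(a, b).sum())
    return inter / union if union else 0.0


def dilate_mask(mask: np.ndarray, k: int) -> np.ndarray:
    """k-fold dilation with a 3x3 square element (Chebyshev k-ball)."""
    if k <= 0:
        return np.asarray(mask).astype(bool)
    return ndimage.binary_dilation(
        np.asarray(mask).astype(bool), structure=np.ones((3, 3), bool), iterations=k
    )


def _same_section(a, b) -> bool:
    if isinstance(a, DetectionBox) and isinstance(b, DetectionBox):
        return a.section == b.section
    return True


def match_detections(
    preds: Sequence,
    truths: Sequence,
    overlap_min: float = 0.7,
    scores: Sequence[float] | None = None,
    overlap_kind: str = "iou",
    dilate_px: int = 0,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truths.

    Predictions are visited in descending score order; each is matched to
    the highest-overlap unmatched truth whose overlap reaches
    ``overlap_min`` (default 70%).  Overlap is intersection-over-union on
    pixel sets (boxes use exact interval arithmetic); ``overlap_kind="iot"``
    switches to intersection-over-truth.  For mask inputs ``dilate_px``
    dilates both sides before computing overlap (the k-pixel-tolerant
    regime).  Boxes on different sections never match.
    """
    preds = list(preds)
    truths = list(truths)
    if scores is None:
        scores = [p.score if isinstance(p, DetectionBox) else 1.0 for p in preds]
    scores = np.asarray(scores, dtype=float)

    if dilate_px and preds and not isinstance(preds[0], DetectionBox):
        preds = [dilate_mask(p, dilate_px) for p in preds]
        truths = [dilate_mask(t, dilate_px) for t in truths]

    order = np.argsort(-scores, kind="stable")
    matched_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for pi in order:
        p = preds[pi]
        best_ov, best_ti = 0.0, -1
        for ti, t in enumerate(truths):
            if ti in matched_truth or not _same_section(p, t):
                continue
            ov = (
                _box_overlap(p, t, overlap_kind)
                if isinstance(p, DetectionBox)
                else _mask_overlap(p, t, overlap_kind)
            )
            if ov > best_ov:
                best_ov, best_ti = ov, ti
        if best_ti >= 0 and best_ov >= overlap_min:
            matched_truth.add(best_ti)
            pairs.append((int(pi), best_ti))
    tp = len(pairs)
    return MatchResult(
        true_positives=tp,
        false_positives=len(preds) - tp,
        false_negatives=len(truths) - tp,
        pairs=pairs,
    )


def precision_recall(
    preds: Sequence,
    truths: Sequence,
    overlap_min: float = 0.7,
    scores: Sequence[float] | None = None,
    overlap_kind: str = "iou",
    dilate_px: int = 0,
) -> PRCurve:
    """Sweep the score threshold (descending) and compute (R, P) points.

    With no predictions the curve is the single point (R=0, P=1) —
    precision is undefined there and reported as 1 by convention.
    """
    preds = list(preds)
    if scores is None:
        scores = [p.score if isinstance(p, DetectionBox) else 1.0 for p in preds]
    scores = np.asarray(scores, dtype=float)
    if not preds:
        return PRCurve(
            recalls=np.array([0.0]), precisions=np.array([1.0]),
            thresholds=np.array([np.inf]),
        )
    levels = np.unique(scores)[::-1]
    rs, ps = [], []
    for t in levels:
        keep = scores >= t
        sub = [p for p, k in zip(preds, keep) if k]
        res = match_detections(
            sub, truths, overlap_min, scores=scores[keep],
            overlap_kind=overlap_kind, dilate_px=dilate_px,
        )
        rs.append(res.recall)
        ps.append(res.precision)
    return PRCurve(
        recalls=np.asarray(rs), precisions=np.asarray(ps), thresholds=levels
    )


def average_precision(curve: PRCurve) -> float:
    """Step-function integral of precision over recall (no interpolation)."""
    r = np.concatenate([[0.0], curve.recalls])
    ap = float(np.sum(curve.precisions * np.diff(r)))
    return ap


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; defined as 0 at (0, 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Pixel-wise Jaccard index |X ∩ Y| / |X ∪ Y|; 1 when both are empty."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    union = int(np.logical_or(x, y).sum())
    if union == 0:
        return 1.0
    inter = int(np.logical_and(x, y).sum())
    return inter / union


def jaccard_k(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Boundary-tolerant Jaccard index with k-pixel dilation.

    ``((X^k ∩ Y) ∪ (X ∩ Y^k)) / (X ∪ Y)`` where ``X^k`` is X dilated k
    times by a 3x3 square element; k = 0 reduces to :func:`jaccard`.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    union = int(np.logical_or(x, y).sum())
    if union == 0:
        return 1.0
    xk = dilate_mask(x, k)
    yk = dilate_mask(y, k)
    numer = int(np.logical_or(xk & y, x & yk).sum())
    return numer / union
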