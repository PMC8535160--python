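"""Centroid matching and detection metrics.

A detection is a true positive when it falls inside the golden-standard
region (a disc of fixed radius) of an annotated centroid and is the closest
such detection; matching is one-to-one and resolved globally greedily in
ascending distance order. Precision, recall and F1 follow the usual
definitions; localization accuracy is summarized by the median and quartiles
of the true-positive distances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .annotations import PointAnnotationSet
from .localization import DetectionSet

__all__ = [
    "MatchParams",
    "MatchResult",
    "Metrics",
    "match_detections",
    "compute_metrics",
    "f1_from_pr",
    "distance_quartiles",
    "aggregate_matches",
    "write_report",
]


@dataclass(frozen=True)
class MatchParams:
    """golden_radius: radius (pixels) of the disc around each annotated
    centroid within which a detection can count as a true positive
    (6 suits H&E-like data at benchmark scale, 10 the fluorescence-like set)."""

    golden_radius: float = 6.0

    def __post_init__(self):
        if not self.golden_radius > 0:
            raise ValueError("golden_radius must be positive")


@dataclass
class MatchResult:
    tp_pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (det, gt, dist)
    fp: list[int] = field(default_factory=list)  # unmatched detection indices
    fn: list[int] = field(default_factory=list)  # unmatched ground-truth indices

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def distances(self) -> np.ndarray:
        return np.asarray([d for _, _, d in self.tp_pairs], dtype=float)


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float
    median: float
    q1: float
    q3: float
    tp: int
    fp: int
    fn: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "degenerate": self.degenerate,
        }


def match_detections(
    dets: DetectionSet | np.ndarray,
    gts: PointAnnotationSet | np.ndarray,
    params: MatchParams = MatchParams(),
) -> MatchResult:
    """One-to-one greedy assignment in ascending distance order.

    Only pairs within the golden radius are candidates; leftover detections
    become false positives and leftover ground-truth points false negatives.
    Distance ties are broken by (detection index, ground-truth index) so the
    result is deterministic.
    """
    det_xy = dets.coords if isinstance(dets, DetectionSet) else np.asarray(dets, float).reshape(-1, 2)
    gt_xy = gts.points if isinstance(gts, PointAnnotationSet) else np.asarray(gts, float).reshape(-1, 2)
    n_det, n_gt = len(det_xy), len(gt_xy)
    result = MatchResult()
    if n_det and n_gt:
        dist = cdist(det_xy, gt_xy)
        cand = [
            (dist[i, j], i, j)
            for i in range(n_det)
            for j in range(n_gt)
            if dist[i, j] <= params.golden_radius
        ]
        cand.sort()
        used_det: set[int] = set()
        used_gt: set[int] = set()
        for d, i, j in cand:
            if i in used_det or j in used_gt:
                continue
            used_det.add(i)
            used_gt.add(j)
            result.tp_pairs.append((i, j, float(d)))
    matched_det = {i for i, _, _ in result.tp_pairs}
    matched_gt = {j for _, j, _ in result.tp_pairs}
    result.fp = [i for i in range(n_det) if i not in matched_det]
    result.fn = [j for j in range(n_gt) if j not in matched_gt]
    return result


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def distance_quartiles(match: MatchResult) -> tuple[float, float, float]:
    """(median, Q1, Q3) of true-positive distances, linearly interpolated;
    NaNs when there are no true positives."""
    d = match.distances
    if d.size == 0:
        return (float("nan"), float("nan"), float("nan"))
    q1, med, q3 = np.percentile(d, [25, 50, 75], method="linear")
    return (float(med), float(q1), float(q3))


def compute_metrics(match: MatchResult) -> Metrics:
    tp, fp, fn = match.tp, len(match.fp), len(match.fn)
    n_det, n_gt = tp + fp, tp + fn
    degenerate = False
    if n_det == 0 and n_gt == 0:
        # nothing to detect and nothing detected: perfect by convention
        p = r = f1 = 1.0
    else:
        if n_det == 0 or n_gt == 0:
            degenerate = True
        p = tp / n_det if n_det else 0.0
        r = tp / n_gt if n_gt else 0.0
        f1 = f1_from_pr(p, r)
    med, q1, q3 = distance_quartiles(match)
    return Metrics(p, r, f1, med, q1, q3, tp, fp, fn, degenerate)


def aggregate_matches(matches: list[MatchResult]) -> Metrics:
    """Micro-averaged metrics over several images (TP/FP/FN pooled)."""
    pooled = MatchResult()
    offset_det = offset_gt = 0
    for m in matches:
        pooled.tp_pairs.extend((i + offset_det, j + offset_gt, d) for i, j, d in m.tp_pairs)
        pooled.fp.extend(i + offset_det for i in m.fp)
        pooled.fn.extend(j + offset_gt for j in m.fn)
        offset_det += m.tp + len(m.fp)
        offset_gt += m.tp + len(m.fn)
    return compute_metrics(pooled)


def write_report(
    path: str | Path,
    summary: Metrics,
    per_image: dict[str, Metrics] | None = None,
) -> None:
    """JSON summary of detection performance (plus optional per-image table)."""
    payload: dict = {"summary": summary.to_dict()}
    if per_image:
        payload["per_image"] = {k: m.to_dict() for k, m in per_image.items()}
    Path(path).write_text(json.dumps(payload, indent=1))
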