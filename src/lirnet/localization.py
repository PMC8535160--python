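"""Turn a density map into nucleus centroids.

The map's integral (rounded to the nearest integer) gives the count N; the
top N local maxima are then extracted greedily: take the current global
maximum, record it, and erase every density value within a circular
neighborhood of radius ``r`` around it (a simplified non-maximum
suppression). Extraction stops early if the map is exhausted, so spurious
zero-score detections are never emitted. Ties between equal maxima are
broken by row-major scan order, making the output deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import DensityMap

__all__ = [
    "LocalizationParams",
    "DetectionSet",
    "count_from_density",
    "localize",
    "default_nms_radius",
    "write_detections_csv",
    "read_detections_csv",
]


@dataclass(frozen=True)
class LocalizationParams:
    """nms_radius: erasure radius r in pixels; count_override replaces the
    integral-derived N when given."""

    nms_radius: float = 5.0
    count_override: int | None = None

    def __post_init__(self):
        if self.nms_radius < 1:
            raise ValueError("nms_radius must be >= 1")


@dataclass
class DetectionSet:
    """Predicted centroids with the density value at each maximum as score."""

    detections: list[tuple[int, int, float]] = field(default_factory=list)
    image_id: str = ""

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def coords(self) -> np.ndarray:
        if not self.detections:
            return np.zeros((0, 2), dtype=float)
        return np.asarray([(r, c) for r, c, _ in self.detections], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return np.asarray([s for _, _, s in self.detections], dtype=float)


def default_nms_radius(kernel_size: int) -> int:
    """Half the object-area kernel, rounded up."""
    return max(1, math.ceil(kernel_size / 2))


def count_from_density(D) -> int:
    """Nearest-integer count from the map integral (half rounds up, floor at 0)."""
    total = D.total if isinstance(D, DensityMap) else float(np.asarray(D).sum())
    return max(0, int(math.floor(total + 0.5)))


def localize(D, params: LocalizationParams) -> DetectionSet:
    """Greedy top-N maxima extraction with circular erasure."""
    if isinstance(D, DensityMap):
        vals, image_id = D.values.copy(), D.image_id
    else:
        vals, image_id = np.asarray(D, dtype=np.float64).copy(), ""
    n = params.count_override if params.count_override is not None else count_from_density(vals)
    h, w = vals.shape
    r = params.nms_radius
    ir = int(math.floor(r))
    dr, dc = np.mgrid[-ir : ir + 1, -ir : ir + 1]
    disk = (dr**2 + dc**2) <= r**2
    dets: list[tuple[int, int, float]] = []
    for _ in range(n):
        idx = int(np.argmax(vals))  # first occurrence in row-major order
        score = float(vals.flat[idx])
        if score <= 0.0:
            break
        pr, pc = divmod(idx, w)
        dets.append((pr, pc, score))
        r0, r1 = max(pr - ir, 0), min(pr + ir + 1, h)
        c0, c1 = max(pc - ir, 0), min(pc + ir + 1, w)
        vals[r0:r1, c0:c1][disk[r0 - pr + ir : r1 - pr + ir, c0 - pc + ir : c1 - pc + ir]] = 0.0
    return DetectionSet(dets, image_id=image_id)


def write_detections_csv(path: str | Path, detection_sets: list[DetectionSet]) -> None:
    import pandas as pd

    rows = [
        {"image_id": ds.image_id, "row": r, "col": c, "score": s}
        for ds in detection_sets
        for r, c, s in ds.detections
    ]
    pd.DataFrame(rows, columns=["image_id", "row", "col", "score"]).to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> list[DetectionSet]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for image_id, sub in df.groupby("image_id", sort=True):
        dets = [
            (int(r), int(c), float(s))
            for r, c, s in zip(sub["row"], sub["col"], sub["score"])
        ]
        out.append(DetectionSet(dets, image_id=str(image_id)))
    return out
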