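"""Ground-truth construction from nucleus point annotations.

Two supervision regimes are supported:

* **Full supervision (FSL)** — each annotated centroid spawns a square
  *object area* of ``kernel_size x kernel_size`` pixels; everything outside
  the union of object areas is one merged *background* region. The training
  loss constrains the density integral over each object area to 1 and over
  the background to 0.
* **Weak supervision (WSL)** — the image is gridded into patches and each
  labeled patch carries a truncated counting indicator ``I in {0, 1, 2}``
  meaning zero, one, or "two or more" nuclei. Large patches (default
  100x100) are all labeled; large patches with ``I=2`` are subdivided into
  small patches (default 20x20) of which a random subset is labeled.

Coordinates are 0-based ``(row, col)`` with a point at a pixel's center.
All rectangles are half-open ``[r0, r1) x [c0, c1)`` so every pixel (and
every boundary point) belongs to exactly one grid cell.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "PointAnnotationSet",
    "SupervisionMask",
    "Patch",
    "PatchLabelSet",
    "mean_two_nn_distance",
    "kernel_size_from_distance",
    "build_supervision_mask",
    "patch_labels_from_points",
    "annotation_cost",
    "read_points_csv",
    "write_points_csv",
]


@dataclass(frozen=True)
class PointAnnotationSet:
    """Nucleus centroid annotations for one image."""

    image_id: str
    points: np.ndarray  # (N, 2) float array of (row, col)
    image_shape: tuple[int, int]

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        h, w = self.image_shape
        if pts.size and (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() >= h
            or pts[:, 1].max() >= w
        ):
            raise ValueError("annotation points must lie within [0, H) x [0, W)")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class SupervisionMask:
    """Discrete object areas plus merged background for one image.

    ``object_rects`` stores each (possibly edge-clipped) kernel square as a
    half-open rectangle ``(r0, r1, c0, c1)``. Overlapping squares are kept
    as-is: a pixel covered by two kernels contributes to both object sums.
    ``s_object`` is the *nominal* kernel area (kernel_size squared) even for
    clipped edge objects, since a clipped object still represents one
    nucleus whose local integral should be 1.
    """

    image_shape: tuple[int, int]
    object_rects: list[tuple[int, int, int, int]]
    kernel_size: int
    _background: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_objects(self) -> int:
        return len(self.object_rects)

    @property
    def s_object(self) -> int:
        return self.kernel_size * self.kernel_size

    @property
    def background(self) -> np.ndarray:
        """Boolean H x W array: True where no object area covers the pixel."""
        if self._background is None:
            mask = np.ones(self.image_shape, dtype=bool)
            for r0, r1, c0, c1 in self.object_rects:
                mask[r0:r1, c0:c1] = False
            self._background = mask
        return self._background

    @property
    def s_background(self) -> int:
        return int(self.background.sum())

    def object_pixel_sets(self) -> list[set[tuple[int, int]]]:
        """Each object area as an explicit pixel set (mainly for inspection)."""
        out = []
        for r0, r1, c0, c1 in self.object_rects:
            out.append({(r, c) for r in range(r0, r1) for c in range(c0, c1)})
        return out

    def to_label_image(self) -> np.ndarray:
        """Single-page label image: 0 = background, k = object k (1-based).

        Pixels covered by several objects take the highest object index; use
        :meth:`to_label_stack` to preserve overlaps.
        """
        lab = np.zeros(self.image_shape, dtype=np.int32)
        for k, (r0, r1, c0, c1) in enumerate(self.object_rects, start=1):
            lab[r0:r1, c0:c1] = k
        return lab

    def to_label_stack(self) -> np.ndarray:
        """One binary page per object (N_O x H x W), preserving overlaps."""
        stack = np.zeros((self.n_objects, *self.image_shape), dtype=np.uint8)
        for k, (r0, r1, c0, c1) in enumerate(self.object_rects):
            stack[k, r0:r1, c0:c1] = 1
        return stack


@dataclass(frozen=True)
class Patch:
    rect: tuple[int, int, int, int]  # half-open (r0, r1, c0, c1)
    level: str  # "large" | "small"
    indicator: int  # 0, 1 or 2


@dataclass
class PatchLabelSet:
    """Patch-level truncated counting indicators for one image."""

    image_shape: tuple[int, int]
    large_size: int
    small_size: int
    patches: list[Patch]
    selection_seed: int | None = None

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def to_json(self) -> str:
        payload = {
            "image_shape": list(self.image_shape),
            "large_size": self.large_size,
            "small_size": self.small_size,
            "selection_seed": self.selection_seed,
            "patches": [
                {
                    "row0": p.rect[0],
                    "row1": p.rect[1],
                    "col0": p.rect[2],
                    "col1": p.rect[3],
                    "level": p.level,
                    "indicator": p.indicator,
                }
                for p in self.patches
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PatchLabelSet":
        d = json.loads(text)
        patches = [
            Patch(
                (p["row0"], p["row1"], p["col0"], p["col1"]),
                p["level"],
                int(p["indicator"]),
            )
            for p in d["patches"]
        ]
        return cls(
            tuple(d["image_shape"]),
            d["large_size"],
            d["small_size"],
            patches,
            d.get("selection_seed"),
        )


def mean_two_nn_distance(annotations: list[PointAnnotationSet] | PointAnnotationSet) -> float:
    """Mean over all nuclei of the average distance to their 2 nearest neighbors.

    Images with fewer than 3 points cannot contribute (a point needs two
    distinct neighbors) and are skipped. This statistic sets the object-area
    kernel size; averaging two neighbors damps the effect of accidental
    duplicate annotations on the same nucleus.
    """
    if isinstance(annotations, PointAnnotationSet):
        annotations = [annotations]
    per_point: list[float] = []
    for ann in annotations:
        if len(ann) < 3:
            continue
        d = cdist(ann.points, ann.points)
        np.fill_diagonal(d, np.inf)
        two_nn = np.sort(d, axis=1)[:, :2]
        per_point.extend(two_nn.mean(axis=1).tolist())
    if not per_point:
        raise ValueError("need at least one image with >= 3 annotated points")
    return float(np.mean(per_point))


def kernel_size_from_distance(d: float) -> int:
    """Odd integer nearest to ``d`` (ties, i.e. even integers, round upward)."""
    if not d > 0:
        raise ValueError("distance must be positive")
    lo = int(math.floor(d))
    if lo % 2 == 0:
        lo -= 1
    hi = lo + 2
    if lo < 1:
        return 1
    # tie (d exactly halfway, i.e. an even integer) goes to the larger kernel
    return lo if (d - lo) < (hi - d) else hi


def build_supervision_mask(points: PointAnnotationSet, kernel_size: int) -> SupervisionMask:
    """Square object areas centered on each annotation, clipped to bounds."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be an odd integer >= 1")
    h, w = points.image_shape
    half = kernel_size // 2
    rects = []
    for row, col in points.points:
        cr, cc = int(round(row)), int(round(col))
        r0, r1 = max(cr - half, 0), min(cr + half + 1, h)
        c0, c1 = max(cc - half, 0), min(cc + half + 1, w)
        rects.append((r0, r1, c0, c1))
    return SupervisionMask(points.image_shape, rects, kernel_size)


def _grid(extent: int, size: int) -> list[tuple[int, int]]:
    """Half-open 1-D grid cells of ``size`` covering [0, extent); edge cells shrink."""
    return [(a, min(a + size, extent)) for a in range(0, extent, size)]


def _count_in_rect(points: np.ndarray, rect: tuple[int, int, int, int]) -> int:
    if points.size == 0:
        return 0
    r0, r1, c0, c1 = rect
    inside = (
        (points[:, 0] >= r0) & (points[:, 0] < r1) & (points[:, 1] >= c0) & (points[:, 1] < c1)
    )
    return int(inside.sum())


def patch_labels_from_points(
    points: PointAnnotationSet,
    large_size: int = 100,
    small_size: int = 20,
    n_small_labels: int | None = None,
    seed: int = 0,
    drop_subdivided_large: bool = False,
) -> PatchLabelSet:
    """Derive weak patch labels from point annotations.

    Every large patch is labeled with ``I = min(count, 2)``. Large patches
    with ``I = 2`` are gridded into small patches; ``n_small_labels`` of
    those (uniform, without replacement, seeded) are labeled the same way.
    ``n_small_labels=None`` labels every small patch. By default large
    ``I=2`` patches remain in the set alongside their labeled small patches
    (their indicator still supervises); ``drop_subdivided_large=True``
    removes a dense large patch once any of its small patches carries a
    label.
    """
    if large_size % small_size != 0:
        raise ValueError("small_size must divide large_size")
    h, w = points.image_shape
    patches: list[Patch] = []
    small_candidates: list[tuple[int, int, int, int]] = []
    for r0, r1 in _grid(h, large_size):
        for c0, c1 in _grid(w, large_size):
            rect = (r0, r1, c0, c1)
            ind = min(_count_in_rect(points.points, rect), 2)
            patches.append(Patch(rect, "large", ind))
            if ind == 2:
                for sr0, sr1 in _grid(r1 - r0, small_size):
                    for sc0, sc1 in _grid(c1 - c0, small_size):
                        small_candidates.append((r0 + sr0, r0 + sr1, c0 + sc0, c0 + sc1))
    n_avail = len(small_candidates)
    if n_small_labels is None:
        n_pick = n_avail
    else:
        n_pick = int(n_small_labels)
        if n_pick > n_avail:
            warnings.warn(
                f"requested {n_pick} small-patch labels but only {n_avail} are "
                "available; clamping",
                stacklevel=2,
            )
            n_pick = n_avail
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_avail, size=n_pick, replace=False) if n_pick else []
    small_patches = []
    for idx in sorted(int(i) for i in np.atleast_1d(chosen)):
        rect = small_candidates[idx]
        ind = min(_count_in_rect(points.points, rect), 2)
        small_patches.append(Patch(rect, "small", ind))
    if drop_subdivided_large and small_patches:
        def subdivided(large: Patch) -> bool:
            r0, r1, c0, c1 = large.rect
            return large.indicator == 2 and any(
                r0 <= p.rect[0] and p.rect[1] <= r1 and c0 <= p.rect[2] and p.rect[3] <= c1
                for p in small_patches
            )

        patches = [p for p in patches if not subdivided(p)]
    patches.extend(small_patches)
    return PatchLabelSet((h, w), large_size, small_size, patches, selection_seed=seed)


def annotation_cost(labels: PatchLabelSet | PointAnnotationSet) -> int:
    """Annotation effort in mouse clicks.

    A point annotation is one precise click per nucleus; a patch label is one
    judgmental click per labeled patch.
    """
    if isinstance(labels, PointAnnotationSet):
        return len(labels)
    if isinstance(labels, PatchLabelSet):
        return labels.n_patches
    raise TypeError(f"unsupported label container: {type(labels).__name__}")


# ---------------------------------------------------------------------------
# CSV round-trip for point annotations (header: image_id,row,col)
# ---------------------------------------------------------------------------


def write_points_csv(path: str | Path, annotations: list[PointAnnotationSet]) -> None:
    import pandas as pd

    rows = []
    for ann in annotations:
        for r, c in ann.points:
            rows.append({"image_id": ann.image_id, "row": r, "col": c})
    pd.DataFrame(rows, columns=["image_id", "row", "col"]).to_csv(path, index=False)


def read_points_csv(
    path: str | Path, image_shapes: dict[str, tuple[int, int]]
) -> list[PointAnnotationSet]:
    """Load point annotations; ``image_shapes`` maps image_id to (H, W)."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for image_id, shape in image_shapes.items():
        sub = df[df["image_id"] == image_id]
        pts = sub[["row", "col"]].to_numpy(dtype=float)
        out.append(PointAnnotationSet(image_id, pts, shape))
    return out
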