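"""Training objectives for density-map nuclei detection.

Full supervision (point annotations turned into object areas ``O_k`` plus a
merged background ``B``):

* ``fsl_loss_l2tanh`` — weighted sum of a squared local-integral object term
  and a tanh-compressed mean background integral,
  ``lambda * (1/N_O) * sum_k (sum_{O_k} D - 1)^2
  + (1 - lambda) * tanh((S_O / S_B) * sum_B D)``.
* ``fsl_loss_l1`` — the hyperparameter-free l1 form,
  ``sum_k |sum_{O_k} D - 1| + sum_B D`` (the background term is a plain sum,
  valid because D >= 0).
* ``per_loss`` — the pixel-wise Euclidean baseline against a Gaussian
  pseudo-density ground truth, ``||D - D_gt||_F^2``.

Weak supervision (patch-level truncated counting indicators I in {0,1,2}):
each patch's predicted count ``C = sum_P D`` is passed through a truncation
``T(C) = C`` below 2 and ``2 + gamma * C`` at or above 2 (the small slope
``gamma`` avoids vanishing gradients on dense patches), compared to its
indicator with either an l2/tanh or an l1 per-patch loss, and the mean is
regularized by ``eta * max(D_max - 1, 0)`` which bounds the otherwise
monotonically decreasing I=2 term.

Every loss also exposes the gradient with respect to the density map via
``return_grad=True``; the trainer consumes those directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import PatchLabelSet, PointAnnotationSet, SupervisionMask
from .model import DensityMap

__all__ = [
    "FSLLossParams",
    "WSLLossParams",
    "GaussianGTParams",
    "fsl_loss_l2tanh",
    "fsl_loss_l1",
    "gaussian_density_map",
    "per_loss",
    "truncate_count",
    "patch_count",
    "wsl_patch_loss_l2tanh",
    "wsl_patch_loss_l1",
    "density_regularizer",
    "wsl_total_loss",
]

LOSS_FORMS = ("fsl_l2tanh", "fsl_l1", "per_baseline", "wsl_l2tanh", "wsl_l1")


@dataclass(frozen=True)
class FSLLossParams:
    """lam: weight balancing object vs background terms in the l2/tanh loss."""

    lam: float = 0.1

    def __post_init__(self):
        if not 0 < self.lam < 1:
            raise ValueError("lam must lie in (0, 1)")


@dataclass(frozen=True)
class WSLLossParams:
    """gamma: truncation slope past a count of 2; eta: max-density regularizer weight."""

    gamma: float = 1e-4
    eta: float = 1e-3

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


@dataclass(frozen=True)
class GaussianGTParams:
    """sigma (pixels) of the per-point Gaussian in the baseline's pseudo ground truth."""

    sigma: float
    truncation: float = 3.0  # support radius in units of sigma

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    @classmethod
    def from_kernel_size(cls, kernel_size: int) -> "GaussianGTParams":
        return cls(sigma=kernel_size / 4.0)


def _values(D) -> np.ndarray:
    return D.values if isinstance(D, DensityMap) else np.asarray(D, dtype=np.float64)


def fsl_loss_l2tanh(
    D, mask: SupervisionMask, params: FSLLossParams = FSLLossParams(), return_grad: bool = False
):
    d = _values(D)
    if d.shape != mask.image_shape:
        raise ValueError("density map and supervision mask shapes differ")
    lam = params.lam
    n_o = mask.n_objects
    bg = mask.background
    ratio = mask.s_object / mask.s_background
    bg_sum = float(d[bg].sum())
    tanh_arg = ratio * bg_sum
    obj_sums = [float(d[r0:r1, c0:c1].sum()) for r0, r1, c0, c1 in mask.object_rects]
    obj_term = (
        (1.0 / n_o) * sum((s - 1.0) ** 2 for s in obj_sums) if n_o else 0.0
    )
    value = lam * obj_term + (1.0 - lam) * float(np.tanh(tanh_arg))
    if not return_grad:
        return value
    grad = np.zeros_like(d)
    if n_o:
        for (r0, r1, c0, c1), s in zip(mask.object_rects, obj_sums):
            grad[r0:r1, c0:c1] += lam * 2.0 * (s - 1.0) / n_o
    grad[bg] += (1.0 - lam) * (1.0 - np.tanh(tanh_arg) ** 2) * ratio
    return value, grad


def fsl_loss_l1(D, mask: SupervisionMask, return_grad: bool = False):
    d = _values(D)
    if d.shape != mask.image_shape:
        raise ValueError("density map and supervision mask shapes differ")
    bg = mask.background
    obj_sums = [float(d[r0:r1, c0:c1].sum()) for r0, r1, c0, c1 in mask.object_rects]
    value = sum(abs(s - 1.0) for s in obj_sums) + float(d[bg].sum())
    if not return_grad:
        return value
    grad = np.zeros_like(d)
    for (r0, r1, c0, c1), s in zip(mask.object_rects, obj_sums):
        grad[r0:r1, c0:c1] += np.sign(s - 1.0)
    grad[bg] += 1.0
    return value, grad


def gaussian_density_map(points: PointAnnotationSet, params: GaussianGTParams) -> DensityMap:
    """Pseudo-density ground truth: one unit-mass truncated Gaussian per point.

    Each Gaussian is renormalized over its discrete truncated support so the
    map's integral equals the point count exactly.
    """
    h, w = points.image_shape
    out = np.zeros((h, w), dtype=np.float64)
    sig = params.sigma
    ext = int(np.ceil(params.truncation * sig))
    for cr, cc in points.points:
        r0, r1 = max(int(cr) - ext, 0), min(int(cr) + ext + 2, h)
        c0, c1 = max(int(cc) - ext, 0), min(int(cc) + ext + 2, w)
        rr, cc_ = np.mgrid[r0:r1, c0:c1]
        q = ((rr - cr) ** 2 + (cc_ - cc) ** 2) / (2.0 * sig**2)
        g = np.exp(-q)
        g[q > params.truncation**2 / 2.0] = 0.0
        total = g.sum()
        if total > 0:
            out[r0:r1, c0:c1] += g / total
    return DensityMap(out, image_id=points.image_id)


def per_loss(D, Dgt, return_grad: bool = False):
    """Pixel-wise Euclidean regression error (squared Frobenius norm)."""
    d, g = _values(D), _values(Dgt)
    if d.shape != g.shape:
        raise ValueError("density maps must share a shape")
    diff = d - g
    value = float((diff**2).sum())
    if not return_grad:
        return value
    return value, 2.0 * diff


def truncate_count(C: float, params: WSLLossParams = WSLLossParams()) -> float:
    """Identity below a count of 2; slope-gamma affine at or above 2."""
    if C < 0:
        raise ValueError("counts are non-negative")
    return float(C) if C < 2.0 else 2.0 + params.gamma * float(C)


def _truncate_grad(C: float, params: WSLLossParams) -> float:
    return 1.0 if C < 2.0 else params.gamma


def patch_count(D, rect: tuple[int, int, int, int]) -> float:
    """Density integral over a half-open rectangle (r0, r1, c0, c1)."""
    d = _values(D)
    r0, r1, c0, c1 = rect
    h, w = d.shape
    if not (0 <= r0 <= r1 <= h and 0 <= c0 <= c1 <= w):
        raise ValueError(f"rectangle {rect} outside a {h}x{w} map")
    return float(d[r0:r1, c0:c1].sum())


def wsl_patch_loss_l2tanh(Tval: float, I: int) -> float:
    if I == 0:
        return float(np.tanh(Tval))
    if I == 1:
        return float((Tval - 1.0) ** 2)
    if I == 2:
        return float(np.tanh(2.0 - Tval))
    raise ValueError("indicator must be 0, 1 or 2")


def _wsl_patch_grad_l2tanh(Tval: float, I: int) -> float:
    """d(loss)/dT for the l2/tanh per-patch loss."""
    if I == 0:
        return 1.0 - float(np.tanh(Tval)) ** 2
    if I == 1:
        return 2.0 * (Tval - 1.0)
    return -(1.0 - float(np.tanh(2.0 - Tval)) ** 2)


def wsl_patch_loss_l1(Tval: float, I: int) -> float:
    """l1 per-patch loss; the I=2 branch is signed (2 - T), deliberately
    unbounded below so dense patches keep a usable gradient."""
    if I in (0, 1):
        return abs(float(I) - Tval)
    if I == 2:
        return 2.0 - Tval
    raise ValueError("indicator must be 0, 1 or 2")


def _wsl_patch_grad_l1(Tval: float, I: int) -> float:
    if I in (0, 1):
        return -float(np.sign(I - Tval))
    return -1.0


def density_regularizer(D, return_grad: bool = False):
    """Penalty on densities above 1: max(D_max - 1, 0) (subgradient at the argmax)."""
    d = _values(D)
    dmax = float(d.max()) if d.size else 0.0
    value = max(dmax - 1.0, 0.0)
    if not return_grad:
        return value
    grad = np.zeros_like(d)
    if value > 0:
        idx = np.unravel_index(int(np.argmax(d)), d.shape)
        grad[idx] = 1.0
    return value, grad


def wsl_total_loss(
    D,
    labels: PatchLabelSet,
    params: WSLLossParams = WSLLossParams(),
    form: str = "l1",
    return_grad: bool = False,
):
    """Mean per-patch truncated-counting loss plus the max-density regularizer."""
    if form not in ("l2tanh", "l1"):
        raise ValueError("form must be 'l2tanh' or 'l1'")
    d = _values(D)
    if d.shape != tuple(labels.image_shape):
        raise ValueError("density map and patch labels shapes differ")
    n_p = labels.n_patches
    if n_p == 0:
        raise ValueError("patch label set is empty")
    patch_loss = wsl_patch_loss_l1 if form == "l1" else wsl_patch_loss_l2tanh
    patch_grad = _wsl_patch_grad_l1 if form == "l1" else _wsl_patch_grad_l2tanh
    total = 0.0
    grad = np.zeros_like(d) if return_grad else None
    for p in labels.patches:
        c = patch_count(d, p.rect)
        t = truncate_count(c, params)
        total += patch_loss(t, p.indicator)
        if return_grad:
            gl = patch_grad(t, p.indicator) * _truncate_grad(c, params) / n_p
            r0, r1, c0, c1 = p.rect
            grad[r0:r1, c0:c1] += gl
    if return_grad:
        reg, reg_grad = density_regularizer(d, return_grad=True)
        value = total / n_p + params.eta * reg
        return value, grad + params.eta * reg_grad
    return total / n_p + params.eta * density_regularizer(d)
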