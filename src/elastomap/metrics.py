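"""Recovery-quality metrics, strain-noise injection, and Delentropy.

Delentropy scores the structural complexity of a grayscale field: image
gradients are estimated by central-difference kernels, their joint (dx, dy)
histogram is normalized into the "deldensity" ``p_ij``, and the score is
half the Shannon entropy ``DE = -1/2 sum p_ij log2 p_ij`` (in bits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .forward import StrainField

__all__ = [
    "l2_relative_error",
    "pointwise_abs_error",
    "NoiseSpec",
    "add_strain_noise",
    "DelentropyResult",
    "delentropy",
]


def l2_relative_error(pred: np.ndarray, truth: np.ndarray) -> float:
    """``||pred - truth||_2 / ||truth||_2`` over flattened fields."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    denom = np.linalg.norm(truth)
    if denom == 0:
        raise ValueError("L2 relative error undefined for zero-norm truth")
    return float(np.linalg.norm(pred - truth) / denom)


def pointwise_abs_error(pred: np.ndarray, truth: np.ndarray):
    """Per-point absolute error field and its maximum."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal shape")
    err = np.abs(pred - truth)
    return err, float(err.max())


@dataclass(frozen=True)
class NoiseSpec:
    """White Gaussian strain noise at relative level ``level``.

    Each strain component receives independent zero-mean Gaussian noise with
    standard deviation ``level * std(component)`` (component-wise relative
    convention).
    """

    level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("noise level must be non-negative")


def add_strain_noise(strains: StrainField, spec: NoiseSpec) -> StrainField:
    """Corrupt a strain field with white Gaussian noise (reproducible)."""
    if spec.level == 0:
        return strains
    rng = np.random.default_rng(spec.seed)
    arr = strains.as_array()
    noisy = arr + spec.level * arr.std(axis=0) * rng.standard_normal(arr.shape)
    return StrainField.from_array(strains.points, noisy)


@dataclass(frozen=True)
class DelentropyResult:
    """Delentropy in bits with the underlying deldensity histogram."""

    DE: float
    deldensity: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray


_KERNEL_DX = np.array([[-1.0, 0.0, 1.0]] * 3)


def delentropy(image: np.ndarray, bins: int = 256) -> DelentropyResult:
    """Delentropy of a 2D intensity array.

    Gradients use the central-difference kernel ``[[-1,0,1]]*3`` (and its
    transpose for y), applied as correlation with the boundary trimmed to
    the valid region.  The joint gradient histogram uses ``bins`` cells per
    axis over the observed gradient range and is normalized to sum to 1
    before the entropy sum; the 1/2 factor accounts for gradient symmetry.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2D and at least 3x3")
    dx = correlate(image, _KERNEL_DX, mode="constant")[1:-1, 1:-1]
    dy = correlate(image, _KERNEL_DX.T, mode="constant")[1:-1, 1:-1]

    def _edges(v):
        lo, hi = v.min(), v.max()
        if hi - lo <= 0:
            lo, hi = lo - 0.5, hi + 0.5
        return np.linspace(lo, hi, bins + 1)

    x_edges, y_edges = _edges(dx), _edges(dy)
    counts, _, _ = np.histogram2d(dx.ravel(), dy.ravel(), bins=(x_edges, y_edges))
    p = counts / counts.sum()
    nz = p[p > 0]
    DE = float(-0.5 * np.sum(nz * np.log2(nz)))
    return DelentropyResult(DE=DE, deldensity=p, x_edges=x_edges, y_edges=y_edges)
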