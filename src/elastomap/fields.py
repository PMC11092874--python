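"""Heterogeneous intensity fields and their conversion to element moduli.

Three field sources feed the synthetic experiments:

* draws from a mean-zero Gaussian random field with squared-exponential
  covariance, sampled at mesh nodes (:func:`sample_grf`);
* grayscale tissue images intensity-mapped onto the mesh by bicubic
  interpolation (:func:`image_to_nodal_field`);
* direct user-supplied nodal arrays.

A nodal intensity field ``f`` in ``[0, 1]`` is converted to one Young's
modulus per element by ``E_ele = sum_i f(x_i) + 1`` over the element's three
vertices, giving moduli in ``[1, 4]`` — inside the admissible band ``(1, 5)``
enforced by the sigmoid output transform of the inverse networks and the box
constraint of the adjoint baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.linalg import cholesky
from scipy.spatial.distance import pdist, squareform

from .mesh import TriMesh

__all__ = [
    "GRFSpec",
    "sample_grf",
    "grf_covariance",
    "minmax_normalize",
    "image_to_nodal_field",
    "element_modulus",
]


@dataclass(frozen=True)
class GRFSpec:
    """Parameters of a stationary Gaussian random field.

    ``kernel`` is the covariance family (only the squared-exponential /
    radial-basis kernel is implemented), ``correlation_length`` its length
    scale in domain units, ``variance`` the marginal variance.
    """

    kernel: str = "squared_exponential"
    correlation_length: float = 0.1
    variance: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kernel != "squared_exponential":
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if self.variance <= 0:
            raise ValueError("variance must be positive")


def grf_covariance(r, spec: GRFSpec):
    """Covariance k(r) = sigma^2 * exp(-r^2 / (2 l^2)) at separation ``r``."""
    ell = spec.correlation_length
    return spec.variance * np.exp(-np.asarray(r) ** 2 / (2.0 * ell**2))


def _grf_cholesky(points: np.ndarray, spec: GRFSpec) -> np.ndarray:
    K = grf_covariance(squareform(pdist(points)), spec)
    jitter = 1e-10 * spec.variance
    for _ in range(8):
        try:
            return cholesky(K + jitter * np.eye(len(K)), lower=True)
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError(
        "GRF covariance matrix is not positive definite even after jitter"
    )


def sample_grf(
    mesh: TriMesh, spec: GRFSpec, size: int | None = None
) -> np.ndarray:
    """Draw realizations of the Gaussian random field at the mesh nodes.

    Returns an array of shape ``(n_nodes,)`` (or ``(size, n_nodes)`` when
    ``size`` is given).  Reproducible for a fixed ``spec.seed``.
    """
    L = _grf_cholesky(mesh.nodes, spec)
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((size or 1, mesh.n_nodes))
    fields = z @ L.T
    return fields[0] if size is None else fields


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Rescale an array to [0, 1]; rejects constant input."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        raise ValueError("cannot min-max normalize a constant field")
    return (values - lo) / (hi - lo)


def image_to_nodal_field(
    image: np.ndarray,
    mesh: TriMesh,
    crop: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Map grayscale image intensities onto the mesh nodes.

    The (optionally cropped) image is rescaled to the unit square with pixel
    centers at ``(col + 0.5)/W`` and ``(row + 0.5)/H`` (row 0 maps to y near
    0, i.e. plain array-index orientation), intensities are min-max
    normalized to ``[0, 1]``, and a bicubic spline is evaluated at the node
    coordinates.  The result is clipped back to ``[0, 1]``.

    Parameters
    ----------
    image : 2D array
        Grayscale intensities (any numeric dtype).
    crop : (row0, row1, col0, col1), optional
        Half-open pixel rectangle to extract before mapping.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2D grayscale array")
    if crop is not None:
        r0, r1, c0, c1 = crop
        if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
            raise ValueError(f"crop {crop} outside image bounds {image.shape}")
        image = image[r0:r1, c0:c1]
    h, w = image.shape
    if h < 4 or w < 4:
        raise ValueError("image (or crop) must be at least 4x4 for bicubic mapping")
    intensities = minmax_normalize(image)
    yc = (np.arange(h) + 0.5) / h
    xc = (np.arange(w) + 0.5) / w
    spline = RectBivariateSpline(yc, xc, intensities, kx=3, ky=3, s=0)
    vals = spline.ev(mesh.nodes[:, 1], mesh.nodes[:, 0])
    return np.clip(vals, 0.0, 1.0)


def element_modulus(
    field: np.ndarray, mesh: TriMesh, convention: str = "sum"
) -> np.ndarray:
    """Convert a nodal intensity field to one modulus per element.

    With the default ``"sum"`` convention ``E_ele = f(x1)+f(x2)+f(x3) + 1``,
    mapping intensities in [0, 1] to moduli in [1, 4].  The ``"mean"``
    convention divides the vertex sum by three (range [1, 2]).
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (mesh.n_nodes,):
        raise ValueError(
            f"field has {field.shape} values, mesh has {mesh.n_nodes} nodes"
        )
    if field.min() < -1e-9 or field.max() > 1 + 1e-9:
        raise ValueError("nodal intensities must lie in [0, 1]; normalize first")
    vertex_sum = field[mesh.elements].sum(axis=1)
    if convention == "sum":
        return vertex_sum + 1.0
    if convention == "mean":
        return vertex_sum / 3.0 + 1.0
    raise ValueError(f"unknown convention {convention!r}")
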