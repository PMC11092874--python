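"""Kinematics and hyperelastic constitutive laws (2D).

Three isotropic strain-energy densities are implemented, each with its first
Piola-Kirchhoff stress ``P = dPsi/dF``:

* compressible Neo-Hookean (plane strain or plane stress):
  ``Psi = lam/2 (log J)^2 - mu log J + mu/2 (I1 - 2)``,
  ``P = mu F + (lam log J - mu) F^{-T}``, with Lame parameters derived from
  Young's modulus E and Poisson's ratio nu; plane stress substitutes
  ``lam_bar = 2 lam mu / (lam + 2 mu)``.
* Mooney-Rivlin: ``Psi = mu1/2 (I1 - 2) + mu2/2 (I2 - 2)``,
  ``P = mu1 F + mu2 (I1 F - F C)``.
* Gent: ``Psi = -(mu Jm / 2) ln(1 - (I1 - 2)/Jm)``,
  ``P = mu Jm / (Jm - (I1 - 2)) * F``, diverging as ``I1 - 2`` approaches
  the locking parameter ``Jm``.

All invariants are the 2D ones (``I1 = tr(F^T F)`` equals 2 at rest), and the
Mooney-Rivlin/Gent forms are used exactly as 2D unconstrained models (no
pressure term), so the forward data generator and the inverse losses are
self-consistent.  The spatially unknown parameter is E (Neo-Hookean), mu1
(Mooney-Rivlin) or mu (Gent); each stress is linear in it.

The ``*_components`` functions operate on scalar-like algebra elements
(NumPy arrays, autodiff tensors, dual numbers) via the dispatching math
helpers in :mod:`elastomap.autodiff`, so they can be differentiated through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import log

__all__ = [
    "MODEL_KINDS",
    "MaterialModel",
    "Kinematics",
    "deformation_gradient",
    "green_lagrange_strain",
    "lame_parameters",
    "stress_components",
    "energy_components",
    "strain_energy_and_stress",
    "dstress_dmodulus",
]

MODEL_KINDS = (
    "neo_hookean_plane_strain",
    "neo_hookean_plane_stress",
    "mooney_rivlin",
    "gent",
)


@dataclass(frozen=True)
class MaterialModel:
    """A constitutive family with its known (spatially constant) parameters.

    The spatially varying unknown (E, mu1 or mu depending on ``kind``) is
    *not* stored here; it is passed alongside wherever stress is evaluated.
    ``mu2`` (Mooney-Rivlin) and ``Jm`` (Gent) default to 0.2 and 10 — the
    Gent default keeps the locking bound well above ``I1 - 2 = 1.92``
    reached at 40% equibiaxial stretch.
    """

    kind: str = "neo_hookean_plane_strain"
    nu: float = 0.3
    mu2: float = 0.2
    Jm: float = 10.0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; one of {MODEL_KINDS}")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must satisfy 0 <= nu < 0.5")
        if self.mu2 < 0:
            raise ValueError("mu2 must be non-negative")
        if self.Jm <= 0:
            raise ValueError("Jm must be positive")

    @property
    def unknown_field_name(self) -> str:
        return {
            "neo_hookean_plane_strain": "E",
            "neo_hookean_plane_stress": "E",
            "mooney_rivlin": "mu1",
            "gent": "mu",
        }[self.kind]


@dataclass(frozen=True)
class Kinematics:
    """Deformation measures derived from a displacement gradient.

    All fields are batched: ``F``, ``C`` and ``eps`` have shape
    ``(..., 2, 2)``; ``J``, ``I1``, ``I2`` have shape ``(...)``.
    """

    F: np.ndarray
    C: np.ndarray
    J: np.ndarray
    I1: np.ndarray
    I2: np.ndarray
    eps: np.ndarray


def deformation_gradient(grad_u: np.ndarray) -> Kinematics:
    """Kinematic quantities from a displacement gradient ``(..., 2, 2)``.

    ``F = I + grad_u``; raises on inverted configurations (``det F <= 0``).
    """
    grad_u = np.asarray(grad_u, dtype=float)
    if grad_u.shape[-2:] != (2, 2):
        raise ValueError("grad_u must have trailing shape (2, 2)")
    F = grad_u + np.eye(2)
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(J <= 0):
        raise ValueError(f"inverted element: det F = {J.min():.4g} <= 0")
    C = np.swapaxes(F, -1, -2) @ F
    I1 = C[..., 0, 0] + C[..., 1, 1]
    tr_C2 = (C @ C)[..., 0, 0] + (C @ C)[..., 1, 1]
    I2 = 0.5 * (I1**2 - tr_C2)
    eps = 0.5 * (C - np.eye(2))
    return Kinematics(F=F, C=C, J=J, I1=I1, I2=I2, eps=eps)


def green_lagrange_strain(F: np.ndarray) -> np.ndarray:
    """``eps = (F^T F - I) / 2`` for a batch of deformation gradients."""
    F = np.asarray(F, dtype=float)
    return 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(2))


def lame_parameters(E, nu: float, plane_stress: bool = False):
    """Lame parameters (lam, mu) from Young's modulus and Poisson's ratio.

    Accepts scalar or array ``E`` (and autodiff scalars).  In plane stress
    the effective ``lam_bar = 2 lam mu / (lam + 2 mu)`` replaces ``lam``.
    """
    mu = E * (0.5 / (1.0 + nu))
    lam = E * (nu / ((1.0 + nu) * (1.0 - 2.0 * nu)))
    if plane_stress:
        lam = 2.0 * lam * mu / (lam + 2.0 * mu)
    return lam, mu


# ---------------------------------------------------------------------------
# Generic component-wise formulas (NumPy / autodiff Tensor / dual numbers)
# ---------------------------------------------------------------------------


def _invariants(F11, F12, F21, F22):
    J = F11 * F22 - F12 * F21
    I1 = F11 * F11 + F12 * F12 + F21 * F21 + F22 * F22
    return J, I1


def stress_components(F11, F12, F21, F22, modulus, model: MaterialModel):
    """First Piola-Kirchhoff stress components ``(P11, P12, P21, P22)``.

    ``modulus`` is the model's spatial unknown (E, mu1 or mu).  No locking /
    inversion checks are performed here — use :func:`strain_energy_and_stress`
    for validated NumPy evaluation.
    """
    kind = model.kind
    if kind in ("neo_hookean_plane_strain", "neo_hookean_plane_stress"):
        J, I1 = _invariants(F11, F12, F21, F22)
        lam, mu = lame_parameters(
            modulus, model.nu, plane_stress=(kind == "neo_hookean_plane_stress")
        )
        coef = lam * log(J) - mu
        inv_j = 1.0 / J
        return (
            mu * F11 + coef * F22 * inv_j,
            mu * F12 - coef * F21 * inv_j,
            mu * F21 - coef * F12 * inv_j,
            mu * F22 + coef * F11 * inv_j,
        )
    if kind == "mooney_rivlin":
        mu1, mu2 = modulus, model.mu2
        C11 = F11 * F11 + F21 * F21
        C12 = F11 * F12 + F21 * F22
        C22 = F12 * F12 + F22 * F22
        I1 = C11 + C22
        FC11 = F11 * C11 + F12 * C12
        FC12 = F11 * C12 + F12 * C22
        FC21 = F21 * C11 + F22 * C12
        FC22 = F21 * C12 + F22 * C22
        return (
            mu1 * F11 + mu2 * (I1 * F11 - FC11),
            mu1 * F12 + mu2 * (I1 * F12 - FC12),
            mu1 * F21 + mu2 * (I1 * F21 - FC21),
            mu1 * F22 + mu2 * (I1 * F22 - FC22),
        )
    if kind == "gent":
        _, I1 = _invariants(F11, F12, F21, F22)
        pref = modulus * model.Jm / (model.Jm - (I1 - 2.0))
        return pref * F11, pref * F12, pref * F21, pref * F22
    raise ValueError(f"unknown model kind {kind!r}")


def energy_components(F11, F12, F21, F22, modulus, model: MaterialModel):
    """Strain-energy density on algebra components (see stress_components)."""
    kind = model.kind
    if kind in ("neo_hookean_plane_strain", "neo_hookean_plane_stress"):
        J, I1 = _invariants(F11, F12, F21, F22)
        lam, mu = lame_parameters(
            modulus, model.nu, plane_stress=(kind == "neo_hookean_plane_stress")
        )
        lj = log(J)
        return 0.5 * lam * lj * lj - mu * lj + 0.5 * mu * (I1 - 2.0)
    if kind == "mooney_rivlin":
        mu1, mu2 = modulus, model.mu2
        C11 = F11 * F11 + F21 * F21
        C12 = F11 * F12 + F21 * F22
        C22 = F12 * F12 + F22 * F22
        I1 = C11 + C22
        tr_C2 = C11 * C11 + 2.0 * C12 * C12 + C22 * C22
        I2 = 0.5 * (I1 * I1 - tr_C2)
        return 0.5 * mu1 * (I1 - 2.0) + 0.5 * mu2 * (I2 - 2.0)
    if kind == "gent":
        _, I1 = _invariants(F11, F12, F21, F22)
        return -0.5 * modulus * model.Jm * log(1.0 - (I1 - 2.0) / model.Jm)
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# Validated vectorized NumPy API
# ---------------------------------------------------------------------------


def _check_admissible(F: np.ndarray, model: MaterialModel):
    J, I1 = _invariants(F[..., 0, 0], F[..., 0, 1], F[..., 1, 0], F[..., 1, 1])
    if model.kind.startswith("neo_hookean") and np.any(J <= 0):
        raise ValueError(f"det F must be positive (min {np.min(J):.4g})")
    if model.kind == "gent" and np.any(I1 - 2.0 >= model.Jm):
        raise ValueError(
            f"Gent locking: I1 - 2 = {np.max(I1) - 2.0:.4g} >= Jm = {model.Jm}"
        )


def strain_energy_and_stress(F: np.ndarray, modulus, model: MaterialModel):
    """Energy density and first PK stress for a batch of ``F`` (..., 2, 2).

    Returns ``(psi, P)`` with ``psi`` shaped ``(...)`` and ``P`` shaped
    ``(..., 2, 2)``.  Raises on inverted (Neo-Hookean) or locking (Gent)
    states.
    """
    F = np.asarray(F, dtype=float)
    modulus = np.asarray(modulus, dtype=float)
    _check_admissible(F, model)
    args = (F[..., 0, 0], F[..., 0, 1], F[..., 1, 0], F[..., 1, 1], modulus, model)
    psi = energy_components(*args)
    P = np.stack(stress_components(*args), axis=-1).reshape(F.shape)
    return psi, P


def dstress_dmodulus(F: np.ndarray, model: MaterialModel) -> np.ndarray:
    """Derivative of P with respect to the spatial unknown, shape (..., 2, 2).

    All three stresses are linear in their unknown modulus, so this is
    independent of its value.
    """
    F = np.asarray(F, dtype=float)
    if model.kind.startswith("neo_hookean"):
        _, P = strain_energy_and_stress(F, 1.0, model)
        return P
    if model.kind == "mooney_rivlin":
        return F.copy()
    if model.kind == "gent":
        _, I1 = _invariants(F[..., 0, 0], F[..., 0, 1], F[..., 1, 0], F[..., 1, 1])
        return (model.Jm / (model.Jm - (I1 - 2.0)))[..., None, None] * F
    raise ValueError(f"unknown model kind {model.kind!r}")
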