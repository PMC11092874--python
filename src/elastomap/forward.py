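"""Static hyperelastic forward solver on the triangulated unit square.

A total-Lagrangian P1 finite-element discretization: the deformation
gradient is constant per element, equilibrium is the weak form of
``Div P = 0`` with the full displacement vector prescribed on the entire
boundary (equibiaxial stretch ``u = (d(2x-1), d(2y-1))``), and the nonlinear
system is solved by Newton iterations under uniform load increments.  The
consistent tangent is assembled from a central finite-difference
linearization of the stress ``dP/dF``, which keeps the solver uniform across
constitutive models.

Nodal Green-Lagrange strains — the training data of the inverse methods —
are recovered from the converged displacement by area-weighted averaging of
the per-element strains onto vertices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import MaterialModel, green_lagrange_strain, strain_energy_and_stress
from .mesh import TriMesh

__all__ = [
    "EquibiaxialBC",
    "StrainField",
    "SolveResult",
    "NonConvergenceError",
    "boundary_displacement",
    "solve_forward",
    "strains_from_displacement",
    "internal_forces",
    "tangent_matrix",
]


class NonConvergenceError(RuntimeError):
    """Newton iterations failed; carries the last residual norm."""

    def __init__(self, message: str, residual_norm: float):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class EquibiaxialBC:
    """Outward boundary displacement ``d`` per side.

    ``d = 0.2`` stretches the unit square by 20% on each side (40% total
    stretch, stretch ratio 1.4).
    """

    d: float = 0.2

    def __post_init__(self):
        if self.d <= -0.5:
            raise ValueError("boundary displacement must exceed -0.5")


@dataclass(frozen=True)
class StrainField:
    """Green-Lagrange strain components at a set of points."""

    points: np.ndarray
    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray

    def __post_init__(self):
        n = len(self.points)
        for name in ("exx", "eyy", "exy"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match point count")

    def as_array(self) -> np.ndarray:
        """Stack the components as an (n_points, 3) array."""
        return np.column_stack([self.exx, self.eyy, self.exy])

    @classmethod
    def from_array(cls, points: np.ndarray, components: np.ndarray) -> "StrainField":
        components = np.asarray(components, dtype=float)
        return cls(
            points=np.asarray(points, dtype=float),
            exx=components[:, 0],
            eyy=components[:, 1],
            exy=components[:, 2],
        )


@dataclass(frozen=True)
class SolveResult:
    u: np.ndarray
    strains: StrainField
    residual_norm: float
    converged: bool
    n_iterations: int


def boundary_displacement(points: np.ndarray, d: float) -> np.ndarray:
    """Equibiaxial Dirichlet data ``u = (d(2x-1), d(2y-1))`` at ``points``."""
    points = np.asarray(points, dtype=float)
    return d * (2.0 * points - 1.0)


def _element_deformation_gradients(mesh, dN, u):
    # F_kj = delta_kj + sum_i u[node_i, k] dN[i, j]
    u_e = u[mesh.elements]  # (E, 3, 2)
    return np.eye(2) + np.einsum("eik,eij->ekj", u_e, dN)


def internal_forces(
    mesh: TriMesh, u: np.ndarray, E: np.ndarray, model: MaterialModel
) -> np.ndarray:
    """Assembled internal nodal forces (the equilibrium residual), (n, 2)."""
    dN = mesh.shape_function_gradients()
    areas = mesh.signed_areas()
    F = _element_deformation_gradients(mesh, dN, u)
    _, P = strain_energy_and_stress(F, E, model)
    fe = np.einsum("e,ekj,eij->eik", areas, P, dN)
    forces = np.zeros_like(u)
    np.add.at(forces, mesh.elements, fe)
    return forces


def _stress_tangent_fd(F, E, model, h=1e-6):
    """dP/dF per element by central differences, shape (E, 2, 2, 2, 2).

    ``D[e, k, q, l, n] = dP_kq / dF_ln``.
    """
    D = np.empty(F.shape[:-2] + (2, 2, 2, 2))
    for l in range(2):
        for n in range(2):
            Fp = F.copy()
            Fp[..., l, n] += h
            Fm = F.copy()
            Fm[..., l, n] -= h
            _, Pp = strain_energy_and_stress(Fp, E, model)
            _, Pm = strain_energy_and_stress(Fm, E, model)
            D[..., l, n] = (Pp - Pm) / (2.0 * h)
    # reorder so D[e, k, q, l, n]: currently D[e, k, q, l, n] already
    return D


def tangent_matrix(
    mesh: TriMesh, u: np.ndarray, E: np.ndarray, model: MaterialModel
) -> sp.csr_matrix:
    """Consistent tangent stiffness (2n x 2n CSR), symmetric up to FD error."""
    dN = mesh.shape_function_gradients()
    areas = mesh.signed_areas()
    F = _element_deformation_gradients(mesh, dN, u)
    D = _stress_tangent_fd(F, E, model)
    # K_e[(i,k),(j,l)] = A_e dN[i,q] D[k,q,l,n] dN[j,n]
    Ke = np.einsum("e,eiq,ekqln,ejn->eikjl", areas, dN, D, dN)
    dofs = (2 * mesh.elements[:, :, None] + np.arange(2)).reshape(-1, 6)
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    K = sp.coo_matrix(
        (Ke.reshape(-1, 36).ravel(), (rows, cols)),
        shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes),
    )
    return K.tocsr()


def solve_forward(
    mesh: TriMesh,
    E: np.ndarray,
    model: MaterialModel,
    bc: EquibiaxialBC,
    tol: float = 1e-8,
    max_newton: int = 25,
    load_steps: int = 5,
    u0: np.ndarray | None = None,
    fallback: bool = True,
) -> SolveResult:
    """Solve the equibiaxial boundary-value problem for a modulus field.

    Parameters
    ----------
    E : ndarray (n_elements,)
        Positive modulus (E, mu1 or mu depending on the model) per element.
    tol : float
        Relative Newton tolerance on the free-dof residual norm per step.
    load_steps : int
        Number of uniform increments of the boundary displacement.
    u0 : ndarray (n_nodes, 2), optional
        Warm-start displacement (e.g. from a previous nearby solve); solved
        in a single Newton loop at full load.
    fallback : bool
        Whether a failed warm start falls back to cold incremental load
        stepping.  Disabled inside the adjoint optimization loop so that a
        diverging forward solve surfaces as such.

    Raises
    ------
    NonConvergenceError
        If a Newton loop fails to converge within ``max_newton`` iterations.
    """
    E = np.asarray(E, dtype=float)
    if E.shape != (mesh.n_elements,):
        raise ValueError("modulus field length must match element count")
    if np.any(E <= 0):
        raise ValueError("all moduli must be positive")

    boundary = mesh.boundary_node_mask()
    free = np.flatnonzero(~np.repeat(boundary, 2))
    g_full = boundary_displacement(mesh.nodes, bc.d)

    def newton(u):
        """Newton loop at full load from an admissible start; returns (u, |r|, iters)."""
        r = internal_forces(mesh, u, E, model).ravel()[free]
        r0 = np.linalg.norm(r)
        residual_norm = r0
        iters = 0
        for _ in range(max_newton):
            if residual_norm <= max(tol * r0, 1e-14):
                return u, residual_norm, iters
            K = tangent_matrix(mesh, u, E, model)[free][:, free]
            du = spla.spsolve(K.tocsc(), -r)
            # backtracking on residual increase or element inversion
            step = 1.0
            for _ in range(8):
                u_try = u.copy()
                u_try.ravel()[free] += step * du
                try:
                    r_try = internal_forces(mesh, u_try, E, model).ravel()[free]
                except ValueError:
                    step *= 0.5
                    continue
                if np.linalg.norm(r_try) < residual_norm or step < 0.1:
                    break
                step *= 0.5
            else:
                raise NonConvergenceError(
                    "line search failed to find an admissible step", residual_norm
                )
            u, r = u_try, r_try
            residual_norm = np.linalg.norm(r)
            iters += 1
        raise NonConvergenceError(
            f"Newton did not converge within {max_newton} iterations "
            f"(residual {residual_norm:.3e})",
            residual_norm,
        )

    total_iters = 0
    if u0 is not None:
        # warm start: try a single solve at full load before falling back
        u = np.array(u0, dtype=float)
        u[boundary] = g_full[boundary]
        try:
            u, residual_norm, total_iters = newton(u)
        except (ValueError, NonConvergenceError) as err:
            if not fallback:
                if isinstance(err, NonConvergenceError):
                    raise
                raise NonConvergenceError(str(err), np.inf) from err
            u0 = None
    if u0 is None:
        u = np.zeros((mesh.n_nodes, 2))
        prev_frac = 0.0
        for frac in np.linspace(0.0, 1.0, load_steps + 1)[1:]:
            # affine predictor: exact for homogeneous bodies, admissible always
            u = u + (frac - prev_frac) * g_full
            u[boundary] = frac * g_full[boundary]
            prev_frac = frac
            u, residual_norm, iters = newton(u)
            total_iters += iters

    strains = strains_from_displacement(mesh, u)
    return SolveResult(
        u=u,
        strains=strains,
        residual_norm=float(residual_norm),
        converged=True,
        n_iterations=total_iters,
    )


def strains_from_displacement(mesh: TriMesh, u: np.ndarray) -> StrainField:
    """Nodal Green-Lagrange strains from a nodal displacement field.

    The per-element (constant) strain is averaged onto vertices with element
    areas as weights; exact for affine displacement fields.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (mesh.n_nodes, 2):
        raise ValueError("u must have shape (n_nodes, 2)")
    dN = mesh.shape_function_gradients()
    areas = mesh.signed_areas()
    F = _element_deformation_gradients(mesh, dN, u)
    eps = green_lagrange_strain(F)  # (E, 2, 2)
    comp = np.stack([eps[:, 0, 0], eps[:, 1, 1], eps[:, 0, 1]], axis=1)
    acc = np.zeros((mesh.n_nodes, 3))
    wacc = np.zeros(mesh.n_nodes)
    np.add.at(acc, mesh.elements.ravel(), np.repeat(comp * areas[:, None], 3, axis=0))
    np.add.at(wacc, mesh.elements.ravel(), np.repeat(areas, 3))
    nodal = acc / wacc[:, None]
    return StrainField(points=mesh.nodes, exx=nodal[:, 0], eyy=nodal[:, 1], exy=nodal[:, 2])
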