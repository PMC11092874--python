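import numpy as np
import pytest

from elastomap.constitutive import MODEL_KINDS, MaterialModel
from elastomap.forward import (
    EquibiaxialBC,
    StrainField,
    boundary_displacement,
    internal_forces,
    solve_forward,
    strains_from_displacement,
)
from elastomap.mesh import make_crossed_mesh


class TestStrainRecovery:
    def test_affine_field_recovered_exactly(self, mesh8):
        u = boundary_displacement(mesh8.nodes, 0.2)
        strains = strains_from_displacement(mesh8, u)
        assert np.allclose(strains.exx, 0.48, atol=1e-14)
        assert np.allclose(strains.eyy, 0.48, atol=1e-14)
        assert np.allclose(strains.exy, 0.0, atol=1e-14)

    def test_rigid_rotation_produces_no_strain(self, mesh8):
        theta = np.deg2rad(10)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        u = mesh8.nodes @ R.T - mesh8.nodes
        strains = strains_from_displacement(mesh8, u)
        assert np.abs(strains.as_array()).max() < 1e-12

    def test_first_order_convergence_on_quadratic_field(self):
        # u = (x^2, x y): analytic eps known; recovery error halves with h
        def strain_error(n):
            mesh = make_crossed_mesh(n)
            x, y = mesh.nodes.T
            u = np.column_stack([x**2, x * y])
            s = strains_from_displacement(mesh, u)
            F11, F12, F21, F22 = 1 + 2 * x, np.zeros_like(x), y, 1 + x
            exx = 0.5 * (F11**2 + F21**2 - 1)
            eyy = 0.5 * (F12**2 + F22**2 - 1)
            exy = 0.5 * (F11 * F12 + F21 * F22)
            interior = ~mesh.boundary_node_mask()
            return np.abs(
                s.as_array()[interior] - np.column_stack([exx, eyy, exy])[interior]
            ).max()

        e8, e16 = strain_error(8), strain_error(16)
        assert e16 < 0.65 * e8


class TestForwardSolve:
    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_homogeneous_body_patch_test(self, kind):
        # affine boundary data on a homogeneous body is an exact equilibrium
        mesh = make_crossed_mesh(8)
        model = MaterialModel(kind=kind, nu=0.3)
        E = np.full(mesh.n_elements, 2.5)
        res = solve_forward(mesh, E, model, EquibiaxialBC(0.2))
        assert res.converged
        assert np.allclose(res.strains.exx, 0.48, atol=1e-8)
        assert np.allclose(res.strains.eyy, 0.48, atol=1e-8)
        assert np.allclose(res.strains.exy, 0.0, atol=1e-8)
        assert np.allclose(res.u, boundary_displacement(mesh.nodes, 0.2), atol=1e-10)

    def test_zero_displacement_is_trivial(self, mesh8, nh_plane_strain):
        E = np.full(mesh8.n_elements, 2.0)
        res = solve_forward(mesh8, E, nh_plane_strain, EquibiaxialBC(0.0))
        assert np.abs(res.u).max() < 1e-14
        assert np.abs(res.strains.as_array()).max() < 1e-14

    def test_global_equilibrium_of_reactions(self, grf_problem):
        # internal forces at interior nodes vanish; reactions sum to zero
        forces = internal_forces(
            grf_problem["mesh"],
            grf_problem["result"].u,
            grf_problem["E_elements"],
            grf_problem["material"],
        )
        interior = ~grf_problem["mesh"].boundary_node_mask()
        assert np.abs(forces[interior]).max() < 1e-10
        assert np.abs(forces.sum(axis=0)).max() < 1e-10

    def test_mirror_symmetry(self, nh_plane_strain):
        # mirroring the modulus field about x = 1/2 mirrors the solution
        mesh = make_crossed_mesh(6)
        rng = np.random.default_rng(4)
        f = rng.random(mesh.n_nodes)
        from elastomap.fields import element_modulus

        E = element_modulus(f, mesh)
        centers = mesh.nodes[mesh.elements].mean(axis=1)
        mirrored_centers = np.column_stack([1 - centers[:, 0], centers[:, 1]])
        order = np.lexsort((centers[:, 1], centers[:, 0]))
        m_order = np.lexsort((mirrored_centers[:, 1], mirrored_centers[:, 0]))
        E_mirror = np.empty_like(E)
        E_mirror[m_order] = E[order]
        res = solve_forward(mesh, E, nh_plane_strain, EquibiaxialBC(0.1))
        res_m = solve_forward(mesh, E_mirror, nh_plane_strain, EquibiaxialBC(0.1))
        # compare nodal exx fields under the mirror map
        nodes_m = np.column_stack([1 - mesh.nodes[:, 0], mesh.nodes[:, 1]])
        n_order = np.lexsort((mesh.nodes[:, 1], mesh.nodes[:, 0]))
        nm_order = np.lexsort((nodes_m[:, 1], nodes_m[:, 0]))
        exx_mapped = np.empty_like(res.strains.exx)
        exx_mapped[nm_order] = res.strains.exx[n_order]
        assert np.allclose(res_m.strains.exx, exx_mapped, atol=1e-9)

    @staticmethod
    def _restrict(coarse_mesh, fine_mesh, fine_values, scale):
        # coarse nodes are a subset of fine nodes when fine = 4x coarse
        key = lambda pts: np.round(pts * scale).astype(int)
        lut = {tuple(k): i for i, k in enumerate(key(fine_mesh.nodes))}
        idx = np.array([lut[tuple(k)] for k in key(coarse_mesh.nodes)])
        return fine_values[idx]

    def test_strains_converge_under_mesh_refinement(self, nh_plane_strain):
        # smooth heterogeneity defined analytically, so every mesh sees the
        # same modulus law; coarse-vs-4x-fine mismatch must shrink with h
        from elastomap.fields import element_modulus

        intensity = lambda p: 0.5 + 0.5 * np.sin(2 * np.pi * p[:, 0]) * np.cos(np.pi * p[:, 1])

        def solve(n):
            mesh = make_crossed_mesh(n)
            E = element_modulus(intensity(mesh.nodes), mesh)
            return mesh, solve_forward(mesh, E, nh_plane_strain, EquibiaxialBC(0.1))

        def refinement_error(nc):
            cm, c = solve(nc)
            fm, f = solve(4 * nc)
            b = self._restrict(cm, fm, f.strains.as_array(), 8 * nc)
            a = c.strains.as_array()
            return np.linalg.norm(a - b) / np.linalg.norm(b)

        e_coarse = refinement_error(10)
        e_fine = refinement_error(20)
        assert e_coarse < 0.08
        assert e_fine < 0.65 * e_coarse  # at least first-order convergence

    def test_two_phase_body_against_fine_mesh(self, nh_plane_strain):
        # left half E=1, right half E=4: strains jump across the interface,
        # where nodal values are averages of the two limits; away from the
        # interface line the coarse and 4x-fine solutions agree closely
        def solve(n):
            mesh = make_crossed_mesh(n)
            centers = mesh.nodes[mesh.elements].mean(axis=1)
            E = np.where(centers[:, 0] < 0.5, 1.0, 4.0)
            return mesh, solve_forward(mesh, E, nh_plane_strain, EquibiaxialBC(0.1))

        coarse_mesh, coarse = solve(10)
        fine_mesh, fine = solve(40)
        b = self._restrict(coarse_mesh, fine_mesh, fine.strains.as_array(), 80)
        a = coarse.strains.as_array()
        off_interface = np.abs(coarse_mesh.nodes[:, 0] - 0.5) > 1e-9
        rel = np.linalg.norm((a - b)[off_interface]) / np.linalg.norm(b[off_interface])
        assert rel < 0.05

    def test_invalid_inputs_rejected(self, mesh8, nh_plane_strain):
        with pytest.raises(ValueError):
            solve_forward(mesh8, np.zeros(mesh8.n_elements), nh_plane_strain, EquibiaxialBC(0.1))
        with pytest.raises(ValueError):
            solve_forward(mesh8, np.ones(3), nh_plane_strain, EquibiaxialBC(0.1))
        with pytest.raises(ValueError):
            EquibiaxialBC(-0.6)


def test_strain_field_container_roundtrip(mesh8):
    arr = np.random.default_rng(0).random((mesh8.n_nodes, 3))
    sf = StrainField.from_array(mesh8.nodes, arr)
    assert np.array_equal(sf.as_array(), arr)
    with pytest.raises(ValueError):
        StrainField(points=mesh8.nodes, exx=arr[:, 0], eyy=arr[:, 1], exy=arr[:5, 2])
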