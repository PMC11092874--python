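import numpy as np
import pytest

from elastomap.constitutive import (
    MODEL_KINDS,
    MaterialModel,
    deformation_gradient,
    dstress_dmodulus,
    lame_parameters,
    strain_energy_and_stress,
)

from conftest import random_admissible_F


def fd_stress(F, modulus, model, h=1e-6):
    """Central finite differences of the energy density w.r.t. F."""
    P = np.zeros_like(F)
    for k in range(2):
        for l in range(2):
            Fp, Fm = F.copy(), F.copy()
            Fp[..., k, l] += h
            Fm[..., k, l] -= h
            psi_p, _ = strain_energy_and_stress(Fp, modulus, model)
            psi_m, _ = strain_energy_and_stress(Fm, modulus, model)
            P[..., k, l] = (psi_p - psi_m) / (2 * h)
    return P


class TestKinematics:
    def test_undeformed_state(self):
        kin = deformation_gradient(np.zeros((2, 2)))
        assert np.allclose(kin.F, np.eye(2))
        assert np.isclose(kin.J, 1.0) and np.isclose(kin.I1, 2.0)
        assert np.isclose(kin.I2, 1.0)
        assert np.allclose(kin.eps, 0.0)

    def test_equibiaxial_stretch_analytics(self):
        kin = deformation_gradient(np.diag([0.4, 0.4]))
        assert np.isclose(kin.J, 1.96)
        assert np.isclose(kin.I1, 3.92)
        assert np.allclose(np.diag(kin.eps), 0.48)
        assert np.isclose(kin.eps[0, 1], 0.0)

    def test_second_invariant_identity(self):
        # in 2D: I2 = 0.5 (I1^2 - tr C^2) must equal det C = J^2
        rng = np.random.default_rng(0)
        grad_u = 0.3 * rng.standard_normal((50, 2, 2))
        keep = np.linalg.det(np.eye(2) + grad_u) > 0.05
        kin = deformation_gradient(grad_u[keep])
        assert np.allclose(kin.I2, kin.J**2, rtol=1e-12)

    def test_inverted_configuration_rejected(self):
        with pytest.raises(ValueError):
            deformation_gradient(np.diag([-1.5, 0.0]))


class TestStressFormulas:
    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_stress_is_energy_gradient(self, kind):
        model = MaterialModel(kind=kind, nu=0.3, mu2=0.2, Jm=10.0)
        rng = np.random.default_rng(7)
        F = random_admissible_F(rng, 1000)
        modulus = rng.uniform(1.0, 5.0, len(F))
        _, P = strain_energy_and_stress(F, modulus, model)
        Pfd = fd_stress(F, modulus, model)
        scale = np.abs(P).max()
        assert np.abs(P - Pfd).max() < 1e-5 * scale

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_objectivity_under_rotations(self, kind):
        model = MaterialModel(kind=kind)
        rng = np.random.default_rng(8)
        F = random_admissible_F(rng, 200)
        theta = rng.uniform(0, 2 * np.pi, len(F))
        Q = np.moveaxis(
            np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            ),
            -1,
            0,
        )
        psi, _ = strain_energy_and_stress(F, 2.0, model)
        psi_rot, _ = strain_energy_and_stress(Q @ F, 2.0, model)
        assert np.allclose(psi, psi_rot, atol=1e-10)

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_linear_homogeneity_in_the_unknown_modulus(self, kind):
        model = MaterialModel(kind=kind, mu2=0.0)  # mu2 scales with mu1
        rng = np.random.default_rng(9)
        F = random_admissible_F(rng, 50)
        _, P1 = strain_energy_and_stress(F, 1.3, model)
        _, P3 = strain_energy_and_stress(F, 3.9, model)
        assert np.allclose(P3, 3.0 * P1, rtol=1e-12)

    def test_neo_hookean_reference_state_is_stress_free(self):
        model = MaterialModel("neo_hookean_plane_strain")
        psi, P = strain_energy_and_stress(np.eye(2), 3.0, model)
        assert np.isclose(psi, 0.0) and np.allclose(P, 0.0)

    def test_neo_hookean_equibiaxial_value(self):
        # frozen from the finite-difference oracle (fd_stress, step 1e-6)
        model = MaterialModel("neo_hookean_plane_strain", nu=0.3)
        F = np.diag([1.4, 1.4])
        _, P = strain_energy_and_stress(F, 3.0, model)
        assert np.allclose(np.diag(P), 1.62307, atol=1e-4)
        assert np.isclose(P[0, 1], 0.0) and np.isclose(P[1, 0], 0.0)
        assert np.abs(P - fd_stress(F, 3.0, model)).max() < 1e-8

    def test_plane_stress_lame_substitution(self):
        lam, mu = lame_parameters(1.0, 0.45)
        lam_ps, mu_ps = lame_parameters(1.0, 0.45, plane_stress=True)
        assert mu_ps == mu
        assert np.isclose(lam_ps, 2 * lam * mu / (lam + 2 * mu))

    def test_mooney_rivlin_reference_state(self):
        model = MaterialModel("mooney_rivlin", mu2=0.2)
        _, P = strain_energy_and_stress(np.eye(2), 1.0, model)
        assert np.allclose(P, (1.0 + 0.2) * np.eye(2))

    def test_mooney_rivlin_degenerates_without_second_term(self):
        model = MaterialModel("mooney_rivlin", mu2=0.0)
        rng = np.random.default_rng(10)
        F = random_admissible_F(rng, 20)
        _, P = strain_energy_and_stress(F, 1.7, model)
        assert np.allclose(P, 1.7 * F, rtol=1e-12)

    def test_gent_reference_and_equibiaxial_prefactor(self):
        model = MaterialModel("gent", Jm=10.0)
        psi, P = strain_energy_and_stress(np.eye(2), 1.0, model)
        assert np.isclose(psi, 0.0) and np.allclose(P, np.eye(2))
        F = np.diag([1.4, 1.4])
        _, P = strain_energy_and_stress(F, 1.0, model)
        assert np.allclose(P, (10.0 / (10.0 - 1.92)) * F, rtol=1e-12)

    def test_gent_locking_raises_and_prefactor_diverges(self):
        model = MaterialModel("gent", Jm=2.0)
        with pytest.raises(ValueError, match="locking"):
            strain_energy_and_stress(np.diag([1.5, 1.5]), 1.0, model)
        # prefactor grows monotonically toward the pole
        stretches = np.sqrt(1 + np.array([1.0, 1.5, 1.9]) / 2)
        norms = [
            np.linalg.norm(strain_energy_and_stress(np.diag([s, s]), 1.0, model)[1])
            for s in stretches
        ]
        assert norms[0] < norms[1] < norms[2]

    def test_small_strain_limit_is_isotropic_elasticity(self):
        # tangent of NH plane strain at F = I: dP = lam tr(H) I + mu (H + H^T)
        model = MaterialModel("neo_hookean_plane_strain", nu=0.3)
        lam, mu = lame_parameters(2.0, 0.3)
        rng = np.random.default_rng(11)
        H = 1e-7 * rng.standard_normal((2, 2))
        _, P = strain_energy_and_stress(np.eye(2) + H, 2.0, model)
        linear = lam * np.trace(H) * np.eye(2) + mu * (H + H.T)
        assert np.allclose(P, linear, atol=1e-12)

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_modulus_sensitivity_matches_fd(self, kind):
        model = MaterialModel(kind=kind)
        rng = np.random.default_rng(12)
        F = random_admissible_F(rng, 30)
        dP = dstress_dmodulus(F, model)
        h = 1e-6
        _, Pp = strain_energy_and_stress(F, 2.0 + h, model)
        _, Pm = strain_energy_and_stress(F, 2.0 - h, model)
        assert np.allclose(dP, (Pp - Pm) / (2 * h), atol=1e-7)


def test_material_model_validation():
    with pytest.raises(ValueError):
        MaterialModel(kind="ogden")
    with pytest.raises(ValueError):
        MaterialModel(nu=0.5)
    with pytest.raises(ValueError):
        MaterialModel(Jm=0.0)
    assert MaterialModel("mooney_rivlin").unknown_field_name == "mu1"
    assert MaterialModel("gent").unknown_field_name == "mu"
    assert MaterialModel().unknown_field_name == "E"
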