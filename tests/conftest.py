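import numpy as np
import pytest

from elastomap.constitutive import MaterialModel
from elastomap.fields import GRFSpec, element_modulus, minmax_normalize, sample_grf
from elastomap.forward import EquibiaxialBC, solve_forward
from elastomap.mesh import make_crossed_mesh


@pytest.fixture(scope="session")
def mesh8():
    return make_crossed_mesh(8)


@pytest.fixture(scope="session")
def nh_plane_strain():
    return MaterialModel("neo_hookean_plane_strain", nu=0.3)


@pytest.fixture(scope="session")
def grf_problem(mesh8, nh_plane_strain):
    """A small heterogeneous reference problem: GRF truth + forward solve."""
    f = minmax_normalize(sample_grf(mesh8, GRFSpec(seed=3)))
    E_el = element_modulus(f, mesh8)
    result = solve_forward(mesh8, E_el, nh_plane_strain, EquibiaxialBC(0.2))
    return {
        "mesh": mesh8,
        "intensity": f,
        "E_elements": E_el,
        "E_nodal": 3.0 * f + 1.0,
        "result": result,
        "bc": EquibiaxialBC(0.2),
        "material": nh_plane_strain,
    }


def random_admissible_F(rng, n, max_offset=0.3):
    """Random deformation gradients with positive determinant."""
    F = np.eye(2) + max_offset * rng.standard_normal((n, 2, 2))
    J = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    keep = J > 0.05
    return F[keep]
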