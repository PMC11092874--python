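import numpy as np
import pytest

from elastomap.autodiff import Tensor
from elastomap.networks import (
    MLP,
    ArchitectureSpec,
    FCNN,
    OutputTransforms,
    apply_output_transforms,
    fourier_features,
    input_features,
    n_parameters,
)


class TestFourierFeatures:
    def test_origin_maps_to_zeros_except_coordinates(self):
        feats = fourier_features(0.0, 0.0)
        assert feats.shape == (1, 12)
        assert np.allclose(feats, 0.0)

    def test_center_point_sine_pattern(self):
        feats = fourier_features(0.5, 0.5)[0]
        expected = [0.5, 0.5, 1, 0, -1, 0, 1, 1, 0, -1, 0, 1]
        assert np.allclose(feats, expected, atol=1e-12)

    def test_x_modes_vanish_on_right_edge(self):
        feats = fourier_features(1.0, 0.37)[0]
        assert np.allclose(feats[2:7], 0.0, atol=1e-12)
        assert feats[0] == 1.0


class TestArchitectureSpec:
    @pytest.mark.parametrize(
        "code, fcnn, fourier, hard_bc",
        [
            ("IIB", "II", False, False),
            ("IA", "I", False, True),
            ("IVC", "IV", True, True),
            ("VD", "V", True, False),
            ("IIID", "III", True, False),
        ],
    )
    def test_code_parsing_roundtrip(self, code, fcnn, fourier, hard_bc):
        spec = ArchitectureSpec.from_code(code)
        assert (spec.fcnn, spec.fourier, spec.hard_bc) == (fcnn, fourier, hard_bc)
        assert spec.code == code

    @pytest.mark.parametrize("bad", ["VIE", "IIX", "B", "VIB", ""])
    def test_invalid_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            ArchitectureSpec.from_code(bad)

    def test_all_twenty_variants_build(self):
        rng_points = np.random.default_rng(0).random((7, 2))
        for fcnn in ("I", "II", "III", "IV", "V"):
            for letter in "ABCD":
                spec = ArchitectureSpec.from_code(fcnn + letter)
                net = FCNN(spec, np.random.default_rng(1))
                feats = input_features(rng_points, spec.fourier)
                out = net.evaluate(feats)
                assert {"ux", "uy", "E"} <= set(out)
                assert ("P" in out) == spec.has_stress_outputs
                assert out["ux"].val.shape == (7,)


class TestTopologies:
    def test_fcnn_v_emits_three_outputs(self):
        spec = ArchitectureSpec.from_code("VB")
        net = FCNN(spec, np.random.default_rng(0))
        assert net.nets["uE"].sizes[-1] == 3

    def test_fcnn_ii_stress_net_emits_five_outputs(self):
        spec = ArchitectureSpec.from_code("IIB")
        net = FCNN(spec, np.random.default_rng(0))
        assert net.nets["EP"].sizes == [2, 75, 75, 75, 75, 75, 5]
        out = net.evaluate(input_features(np.random.random((4, 2)), False))
        assert len(out["P"]) == 4

    def test_fcnn_iv_parameter_count_by_enumeration(self):
        # three independent nets: 2->25, 4x(25->25), 25->1, weights + biases
        expected = 3 * ((2 * 25 + 25) + 4 * (25 * 25 + 25) + (25 * 1 + 1))
        net = FCNN(ArchitectureSpec.from_code("IVB"), np.random.default_rng(0))
        assert n_parameters(net) == expected == 8103

    def test_fourier_variant_widens_input(self):
        net = FCNN(ArchitectureSpec.from_code("IID"), np.random.default_rng(0))
        assert net.nets["u"].sizes[0] == 12

    def test_same_seed_same_initialization(self):
        a = FCNN(ArchitectureSpec.from_code("IIIB"), np.random.default_rng(5))
        b = FCNN(ArchitectureSpec.from_code("IIIB"), np.random.default_rng(5))
        for pa, pb in zip(a.parameters, b.parameters):
            assert np.array_equal(pa.value, pb.value)


class TestDerivativePropagation:
    @pytest.mark.parametrize("fourier", [False, True])
    def test_first_derivatives_match_finite_differences(self, fourier):
        mlp = MLP([12 if fourier else 2, 8, 8, 3], np.random.default_rng(2))
        pts = np.random.default_rng(3).random((20, 2)) * 0.8 + 0.1
        h = 1e-6

        def value(p):
            return mlp.forward(input_features(p, fourier)).val.value

        out = mlp.forward(input_features(pts, fourier))
        fd_x = (value(pts + [h, 0]) - value(pts - [h, 0])) / (2 * h)
        fd_y = (value(pts + [0, h]) - value(pts - [0, h])) / (2 * h)
        assert np.abs(out.dx.value - fd_x).max() < 1e-7
        assert np.abs(out.dy.value - fd_y).max() < 1e-7

    def test_second_derivatives_match_finite_differences(self):
        mlp = MLP([2, 8, 8, 2], np.random.default_rng(4))
        pts = np.random.default_rng(5).random((15, 2)) * 0.8 + 0.1
        h = 1e-4

        def value(p):
            return mlp.forward(input_features(p, False, order=2), order=2).val.value

        out = mlp.forward(input_features(pts, False, order=2), order=2)
        v0 = value(pts)
        fd_xx = (value(pts + [h, 0]) - 2 * v0 + value(pts - [h, 0])) / h**2
        fd_yy = (value(pts + [0, h]) - 2 * v0 + value(pts - [0, h])) / h**2
        fd_xy = (
            value(pts + [h, h]) - value(pts + [h, -h]) - value(pts + [-h, h]) + value(pts - [h, h])
        ) / (4 * h**2)
        assert np.abs(out.dxx.value - fd_xx).max() < 1e-5
        assert np.abs(out.dyy.value - fd_yy).max() < 1e-5
        assert np.abs(out.dxy.value - fd_xy).max() < 1e-5


class TestOutputTransforms:
    def test_modulus_transform_midpoint_and_band(self):
        tr = OutputTransforms.default(0.2, False)
        from elastomap.networks import Bundle

        raw = Bundle(Tensor(np.array([0.0])))
        assert np.isclose(tr.modulus(raw).val.value, 3.0)
        rng = np.random.default_rng(6)
        # scale keeps 4*sigmoid(ne) above float64 resolution at the extremes
        ne = rng.standard_normal(100000) * 6
        _, E = apply_output_transforms(np.zeros((len(ne), 2)), ne, np.zeros((len(ne), 2)), tr)
        assert E.min() > 1.0 and E.max() < 5.0
        order = np.argsort(ne)
        assert np.all(np.diff(E[order]) >= 0)

    def test_modulus_asymptotes(self):
        tr = OutputTransforms.default(0.2, False)
        _, E = apply_output_transforms(
            np.zeros((2, 2)), np.array([-40.0, 40.0]), np.zeros((2, 2)), tr
        )
        assert np.isclose(E[0], 1.0) and np.isclose(E[1], 5.0)

    def test_hard_constraint_is_exact_on_the_boundary(self):
        rng = np.random.default_rng(7)
        n = 1000
        t = rng.random(n)
        side = rng.integers(0, 4, n)
        pts = np.where(
            (side % 2 == 0)[:, None],
            np.column_stack([t, (side // 2).astype(float)]),
            np.column_stack([(side // 2).astype(float), t]),
        )
        tr = OutputTransforms.default(0.2, True)
        raw_u = 10.0 * rng.standard_normal((n, 2))
        u, _ = apply_output_transforms(raw_u, np.zeros(n), pts, tr)
        g = tr.particular(pts)
        assert np.abs(u - g).max() == 0.0

    def test_interior_point_keeps_network_freedom(self):
        tr = OutputTransforms.default(0.2, True)
        pts = np.array([[0.5, 0.5]])
        u1, _ = apply_output_transforms(np.array([[1.0, 0.0]]), [0.0], pts, tr)
        u2, _ = apply_output_transforms(np.array([[2.0, 0.0]]), [0.0], pts, tr)
        assert not np.allclose(u1, u2)

    def test_reference_statistics(self):
        rng = np.random.default_rng(8)
        u_ref = rng.standard_normal((50, 2)) * [0.1, 0.2] + [0.3, -0.1]
        tr = OutputTransforms.from_reference(u_ref, 0.2, False)
        assert np.allclose(tr.u_mean, u_ref.mean(axis=0))
        assert np.allclose(tr.u_std, u_ref.std(axis=0))

    def test_invalid_std_rejected(self):
        with pytest.raises(ValueError):
            OutputTransforms(u_std=np.array([0.0, 1.0]))
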