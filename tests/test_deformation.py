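"""Jacobian-determinant mathematics: analytic families, numerics, encoding."""

import numpy as np
import pytest

from lungjac.deformation import (
    Affine, Compose, DisplacementField, FoldingWarning, JacobianMap,
    RadialBump, SeparableSinusoid, evaluate_analytic, invert_analytic,
    jacobian_determinant, log2_decode, log2_encode,
)
from lungjac.volumes import LungMask, Volume3D


def _grid_template(n=16, spacing=3.0):
    return Volume3D(np.zeros((n, n, n), dtype=np.float32), spacing=(spacing,) * 3)


def _full_mask(n=16, spacing=3.0):
    return LungMask(np.ones((n, n, n), dtype=np.uint8), spacing=(spacing,) * 3)


class TestNumericJacobian:
    def test_zero_displacement_is_identity(self):
        field = DisplacementField(np.zeros((8, 8, 8, 3)), spacing=(3, 3, 3))
        jmap = jacobian_determinant(field, _full_mask(8))
        np.testing.assert_allclose(jmap.J.data, 1.0, atol=1e-7)
        assert not jmap.folded

    def test_linear_displacement_exact(self):
        # u = (0.1 x0, 0, 0) in physical mm -> J = 1.1 exactly (central
        # differences are exact for polynomials of degree <= 2)
        n, sp = 10, 2.0
        x0 = np.arange(n) * sp
        u = np.zeros((n, n, n, 3))
        u[..., 0] = 0.1 * x0[:, None, None]
        jmap = jacobian_determinant(DisplacementField(u, spacing=(sp,) * 3), _full_mask(10, sp))
        np.testing.assert_allclose(jmap.J.data, 1.1, atol=1e-10)

    def test_general_affine_exact(self, rng):
        A = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        n, sp = 8, 3.0
        pts = np.stack(np.meshgrid(*[np.arange(n) * sp] * 3, indexing="ij"), axis=-1)
        u = pts @ (A - np.eye(3)).T
        jmap = jacobian_determinant(DisplacementField(u, spacing=(sp,) * 3), _full_mask(8, sp))
        np.testing.assert_allclose(jmap.J.data, np.linalg.det(A), atol=1e-10)

    def test_sinusoid_against_closed_form(self):
        # u0 = A sin(k x0): numeric central difference error bound A k^3 h^2 / 6
        A, k, h, n = 2.0, 0.1, 3.0, 48
        x0 = np.arange(n) * h
        u = np.zeros((n, n, n, 3))
        u[..., 0] = A * np.sin(k * x0)[:, None, None]
        jmap = jacobian_determinant(DisplacementField(u, spacing=(h,) * 3), _full_mask(48, h))
        exact = 1.0 + A * k * np.cos(k * x0)[:, None, None] * np.ones((n, n, n))
        interior = np.abs(np.asarray(jmap.J.data) - exact)[1:-1]
        assert interior.max() <= A * k**3 * h**2 / 6 + 1e-12

    def test_shape_mismatch(self):
        field = DisplacementField(np.zeros((8, 8, 8, 3)), spacing=(3, 3, 3))
        with pytest.raises(ValueError, match="shape"):
            jacobian_determinant(field, _full_mask(10, 3.0))

    def test_folding_flags_not_raises(self):
        # strong alternating displacement folds the grid
        n, sp = 8, 1.0
        u = np.zeros((n, n, n, 3))
        u[..., 0] = 2.0 * (-1.0) ** np.arange(n)[:, None, None]
        with pytest.warns(FoldingWarning):
            jmap = jacobian_determinant(DisplacementField(u, spacing=(sp,) * 3),
                                        _full_mask(8, sp))
        assert jmap.folded


class TestLog2Encoding:
    def test_round_trip_and_signs(self):
        J = Volume3D(np.array([[[1.0, 2.0, 0.5, 4.0]]], dtype=np.float32))
        Y = log2_encode(J)
        np.testing.assert_allclose(Y.data.ravel(), [0.0, 1.0, -1.0, 2.0], atol=1e-7)
        back = log2_decode(Y)
        np.testing.assert_allclose(back.data, J.data, rtol=1e-6)

    def test_reciprocal_symmetry(self):
        # equal magnitude, opposite sign for J and 1/J
        J = Volume3D(np.full((2, 2, 2), 2.0, dtype=np.float32))
        Jinv = Volume3D(np.full((2, 2, 2), 0.5, dtype=np.float32))
        np.testing.assert_allclose(log2_encode(J).data, -log2_encode(Jinv).data, atol=1e-7)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log2_encode(Volume3D(np.zeros((2, 2, 2))))

    def test_decode_values(self):
        Y = Volume3D(np.array([[[0.0, 1.0, -2.0]]], dtype=np.float32))
        np.testing.assert_allclose(log2_decode(Y).data.ravel(), [1.0, 2.0, 0.25], rtol=1e-6)


class TestAnalyticFamilies:
    def test_affine_scaling_jacobian(self):
        d = Affine.scaling((1.1, 1.2, 1.3))
        _, jmap = evaluate_analytic(d, _grid_template())
        np.testing.assert_allclose(jmap.J.data, 1.1 * 1.2 * 1.3, rtol=1e-6)

    def test_sinusoid_product_form(self, rng):
        # symbolic per-axis factors: J = prod_i (1 + A_i k_i cos(k_i (x_i-c_i)+phi_i))
        import sympy as sp
        amp = rng.uniform(0.5, 2.0, 3)
        freq = rng.uniform(0.05, 0.12, 3)
        phase = rng.uniform(0, 2 * np.pi, 3)
        d = SeparableSinusoid(amp=amp, freq=freq, phase=phase)
        xs = sp.symbols("x0 x1 x2")
        h = [xs[i] + amp[i] * sp.sin(freq[i] * xs[i] + phase[i]) for i in range(3)]
        Jsym = sp.prod([sp.diff(h[i], xs[i]) for i in range(3)])
        f = sp.lambdify(xs, Jsym, "numpy")
        pts = rng.uniform(0, 45, size=(20, 3))
        np.testing.assert_allclose(d.jacobian(pts), f(*pts.T), rtol=1e-10)

    def test_radial_zero_amplitude_is_identity(self):
        d = RadialBump(a=0.0, sigma=5.0, center=(10, 10, 10))
        _, jmap = evaluate_analytic(d, _grid_template())
        np.testing.assert_allclose(jmap.J.data, 1.0, atol=1e-7)

    def test_radial_jacobian_matches_finite_difference(self):
        d = RadialBump(a=0.3, sigma=8.0, center=(20.0, 22.0, 18.0))
        pts = np.random.default_rng(3).uniform(5, 40, size=(10, 3))
        eps = 1e-5
        for p in pts:
            F = np.empty((3, 3))
            for j in range(3):
                dp = np.zeros(3); dp[j] = eps
                F[:, j] = (d(p + dp) - d(p - dp)) / (2 * eps)
            assert d.jacobian(p[None])[0] == pytest.approx(np.linalg.det(F), rel=1e-6)

    def test_positivity_guard(self):
        with pytest.raises(ValueError):
            SeparableSinusoid(amp=(20.0, 0, 0), freq=(0.1, 0.1, 0.1))
        with pytest.raises(ValueError):
            RadialBump(a=1.5, sigma=5.0)


class TestInversion:
    def test_affine_inverse_exact(self):
        d = Affine.scaling(1.5, center=(10, 10, 10))
        g = invert_analytic(d)
        pts = np.random.default_rng(0).uniform(0, 30, size=(50, 3))
        np.testing.assert_allclose(d(g(pts)), pts, atol=1e-12)
        np.testing.assert_allclose(g.jacobian(pts), 1 / 1.5**3, rtol=1e-12)

    def test_identity_inverse(self):
        d = Affine(np.eye(3))
        g = invert_analytic(d)
        pts = np.random.default_rng(0).uniform(0, 30, size=(10, 3))
        np.testing.assert_allclose(g(pts), pts, atol=1e-12)

    @pytest.mark.parametrize("deformation", [
        SeparableSinusoid(amp=(1.5, 1.0, 2.0), freq=(0.1, 0.12, 0.08), phase=(0.3, 1.0, 2.0)),
        RadialBump(a=0.3, sigma=8.0, center=(48, 48, 48)),
        Compose(Affine.scaling(1.3, center=(48, 48, 48)),
                SeparableSinusoid(amp=(1.5, 0.8, 1.2), freq=(0.1, 0.1, 0.1))),
    ])
    def test_composition_residual_below_tolerance(self, deformation):
        g = invert_analytic(deformation)
        n = 32
        pts = np.stack(np.meshgrid(*[np.arange(n) * 3.0] * 3, indexing="ij"),
                       axis=-1).reshape(-1, 3)
        residual = np.abs(deformation(g(pts)) - pts).max()
        assert residual <= 1e-3


class TestPairedFrameProperties:
    def test_reciprocity(self):
        # J_FRC(x) * J_TLC(h(x)) = 1 for an analytic pair
        h = Compose(Affine.scaling(1.2, center=(24, 24, 24)),
                    SeparableSinusoid(amp=(1.0, 0.7, 0.9), freq=(0.08, 0.1, 0.09),
                                      center=(24, 24, 24)))
        pts = np.random.default_rng(1).uniform(6, 42, size=(200, 3))
        j_frc = h.jacobian(pts)
        j_tlc = h.inverse().jacobian(h(pts))
        rel = np.abs(j_frc * j_tlc - 1.0)
        assert np.median(rel) <= 0.01

    def test_integral_property(self, affine_case):
        # mean J_FRC over the FRC mask ~ TLC/FRC mask-volume ratio
        m = affine_case.M_FRC.as_bool()
        mean_j = float(affine_case.J_FRC.J.data[m].mean())
        ratio = affine_case.M_TLC.volume_mm3 / affine_case.M_FRC.volume_mm3
        assert mean_j == pytest.approx(ratio, rel=0.05)


class TestDisplacementFieldIO:
    def test_round_trip(self, tmp_path, rng):
        from lungjac.deformation import read_displacement_field, write_displacement_field
        field = DisplacementField(rng.standard_normal((6, 5, 4, 3)), spacing=(3, 3, 3),
                                  origin=(1, 2, 3), frame="TLC")
        path = write_displacement_field(field, tmp_path / "u.nii.gz")
        back = read_displacement_field(path, frame="TLC")
        np.testing.assert_allclose(back.u, field.u, atol=1e-6)
        assert back.spacing == pytest.approx(field.spacing)

    def test_wrong_component_count(self, tmp_path):
        import nibabel as nib
        from lungjac.deformation import read_displacement_field
        nib.save(nib.Nifti1Image(np.zeros((3, 3, 3, 2), dtype=np.float32), np.eye(4)),
                 str(tmp_path / "u.nii.gz"))
        with pytest.raises(ValueError, match="3 components"):
            read_displacement_field(tmp_path / "u.nii.gz")
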