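"""Derivative evaluation: exactness, finite-difference agreement, cylindrical frame."""

import numpy as np
import pytest

import cedi
from cedi.differentiation import AXIS_EPS, finite_difference_oracle
from cedi.surrogate import AnalyticSurrogate, CapabilityError


def _quadratic_oracle():
    # B = xi1^2, with exact derivatives
    def deriv(pts, axis, order):
        if axis == 0 and order == 1:
            return 2.0 * pts[:, 0]
        if axis == 0 and order == 2:
            return np.full(pts.shape[0], 2.0)
        return np.zeros(pts.shape[0])

    return AnalyticSurrogate(lambda p: p[:, 0] ** 2, deriv)


class TestPartialDerivative:
    def test_polynomial_second_derivative(self, rng):
        pts = rng.uniform(-2, 2, (30, 4))
        out = cedi.partial_derivative(_quadratic_oracle(), pts, (2, 0, 0))
        np.testing.assert_allclose(out, 2.0)

    def test_orthogonal_direction_is_zero(self, rng):
        pts = rng.uniform(-2, 2, (30, 4))
        out = cedi.partial_derivative(_quadratic_oracle(), pts, (0, 0, 1))
        np.testing.assert_allclose(out, 0.0)

    def test_mixed_derivative_unsupported(self, rng):
        pts = rng.uniform(-2, 2, (3, 4))
        model = cedi.build_surrogate(cedi.SurrogateConfig(seed=0))
        with pytest.raises(CapabilityError):
            cedi.partial_derivative(model, pts, (1, 1, 0))
        with pytest.raises(CapabilityError):
            cedi.partial_derivative(model, pts, (3, 0, 0))

    @pytest.mark.parametrize(
        "gamma,wt,h,tol",
        [
            ((1, 0, 0), 0, 1e-4, 1e-5),
            ((0, 1, 0), 0, 1e-4, 1e-5),
            ((0, 0, 0), 1, 1e-4, 1e-5),
            ((2, 0, 0), 0, 1e-3, 1e-3),
            ((0, 0, 2), 0, 1e-3, 1e-3),
        ],
    )
    def test_network_matches_finite_differences(self, gamma, wt, h, tol):
        model = cedi.build_surrogate(cedi.SurrogateConfig(seed=1))
        pts = np.random.default_rng(42).uniform(-2, 2, (100, 4))
        exact = cedi.partial_derivative(model, pts, gamma, wt)
        fd = finite_difference_oracle(model.evaluate, pts, gamma, wt, h)
        rel = np.max(np.abs(exact - fd)) / max(np.max(np.abs(exact)), 1e-12)
        assert rel < tol


class TestCylindrical:
    def test_radially_symmetric_field(self, rng):
        pts = rng.uniform(-2, 2, (50, 4))
        g1, g2 = 2 * pts[:, 0], 2 * pts[:, 1]  # grad of xi1^2 + xi2^2
        dr, dth, mask = cedi.cylindrical_derivatives((g1, g2), pts)
        r = np.hypot(pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(dr[mask], 2 * r[mask], atol=1e-12)
        np.testing.assert_allclose(dth[mask], 0.0, atol=1e-12)

    def test_tangential_field_at_theta_zero(self):
        pts = np.array([[1.0, 0.0, 0.3, 0.2]])
        dr, dth, mask = cedi.cylindrical_derivatives(
            (np.zeros(1), np.ones(1)), pts  # grad of B = xi2
        )
        assert mask[0]
        assert dr[0] == pytest.approx(0.0)
        assert dth[0] == pytest.approx(1.0)

    def test_on_axis_point_masked(self):
        pts = np.array([[0.0, 0.0, 1.0, 0.0], [1.0, 0.0, 0.0, 0.0]])
        _, _, mask = cedi.cylindrical_derivatives((np.ones(2), np.ones(2)), pts)
        assert not mask[0] and mask[1]

    def test_gradient_norm_rotation_invariance(self, adr_oracle, adr_scaled):
        pts = adr_scaled.points()[::7]
        g1 = adr_oracle.input_derivative(pts, 0, 1)
        g2 = adr_oracle.input_derivative(pts, 1, 1)
        dr, dth, mask = cedi.cylindrical_derivatives((g1, g2), pts)
        lhs = dr[mask] ** 2 + dth[mask] ** 2
        rhs = g1[mask] ** 2 + g2[mask] ** 2
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-10 * max(rhs.max(), 1))


class TestFiniteDifferenceOracle:
    def test_sine_first_derivative(self):
        pts = np.zeros((1, 4))
        out = finite_difference_oracle(lambda p: np.sin(p[:, 0]), pts, (1, 0, 0), h=1e-3)
        assert out[0] == pytest.approx(1.0, abs=1e-6)

    def test_exact_for_quadratics(self):
        pts = np.array([[1.3, 0, 0, 0]])
        out = finite_difference_oracle(lambda p: p[:, 0] ** 2, pts, (2, 0, 0), h=0.1)
        assert out[0] == pytest.approx(2.0, abs=1e-9)

    def test_second_order_convergence(self):
        # halving-by-ten the step shrinks the error by ~100 (O(h^2))
        pts = np.array([[0.5, 0, 0, 0]])
        f = lambda p: np.exp(p[:, 0])
        truth = np.exp(0.5)
        err = {
            h: abs(finite_difference_oracle(f, pts, (1, 0, 0), h=h)[0] - truth)
            for h in (1e-2, 1e-3)
        }
        ratio = err[1e-2] / err[1e-3]
        assert 90 < ratio < 110


class TestDerivativeTable:
    def test_catalogue_one_terms_present(self, adr_oracle, adr_scaled):
        cat = cedi.standard_catalogue("I")
        table = cedi.build_derivative_table(
            adr_oracle, adr_scaled.points()[:50], cat.needed_keys()
        )
        for key in ("B", "dB_dxi3", "laplacian"):
            assert key in table
        assert table.dB_dtau.shape == (50,)

    def test_matches_field_closed_forms(self, adr_spec, adr_field, adr_scaling, adr_oracle, adr_scaled):
        # independent route: physical-frame closed forms mapped by hand chain rule
        pts = adr_scaled.points()[::11]
        sp = adr_scaling
        x = pts[:, :3] * sp.sigma_x + sp.x_bar
        t = pts[:, 3] * sp.sigma_t + sp.t_bar
        table = cedi.build_derivative_table(adr_oracle, pts, {"B", "dB_dxi3", "laplacian"})
        expect_dxi3 = adr_field.dx(x, t, 2) * sp.sigma_x[2] / sp.sigma_b
        scale = np.abs(expect_dxi3).max()
        np.testing.assert_allclose(table["dB_dxi3"], expect_dxi3, atol=1e-10 * scale)
        lap = sum(
            adr_field.d2x(x, t, i) * sp.sigma_x[i] ** 2 / sp.sigma_b for i in range(3)
        )
        np.testing.assert_allclose(table["laplacian"], lap, atol=1e-10 * np.abs(lap).max())

    def test_laplacian_is_componentwise_sum(self, adr_oracle, adr_scaled):
        pts = adr_scaled.points()[:40]
        table = cedi.build_derivative_table(adr_oracle, pts, {"laplacian"})
        comp = sum(
            cedi.partial_derivative(adr_oracle, pts, g)
            for g in ((2, 0, 0), (0, 2, 0), (0, 0, 2))
        )
        np.testing.assert_array_equal(table["laplacian"], comp)

    def test_empty_points(self, adr_oracle):
        table = cedi.build_derivative_table(adr_oracle, np.empty((0, 4)), {"B"})
        assert table.dB_dtau.size == 0
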