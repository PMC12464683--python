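"""Catalogues, library normalization, and coefficient scale conversions."""

import dataclasses

import numpy as np
import pytest

import cedi
from cedi.catalogue import (
    DegenerateTermError,
    custom_catalogue,
    load_library,
    normalize_library,
    save_library,
)
from cedi.datasets import ScalingParams
from cedi.differentiation import build_derivative_table
from cedi.surrogate import AnalyticSurrogate


class TestStandardCatalogues:
    def test_catalogue_one(self):
        cat = cedi.standard_catalogue("I")
        assert cat.labels == ("rho", "v3", "d")
        assert [t.term_key for t in cat.terms] == ["B", "dB_dxi3", "laplacian"]

    def test_catalogue_four_has_angular_term(self):
        cat = cedi.standard_catalogue("IV")
        assert cat.n == 5
        assert "vtheta" in cat.labels

    def test_roman_unicode_alias(self):
        assert cedi.standard_catalogue("Ⅲ").labels == ("rho", "vr", "v3", "d")

    def test_unknown_catalogue(self):
        with pytest.raises(KeyError):
            cedi.standard_catalogue("V")

    @pytest.mark.parametrize(
        "cid,expected", [("I", 3), ("II", 5), ("III", 4), ("IV", 5)]
    )
    def test_sizes(self, cid, expected):
        assert cedi.standard_catalogue(cid).n == expected


class TestBuildLibrary:
    def test_shapes(self, lib_I):
        assert lib_I.X.shape == (lib_I.q, 3)
        assert lib_I.Y.shape == (lib_I.q,)

    def test_on_axis_rows_dropped_consistently(self):
        # field with closed-form gradient, and a point set containing the axis
        def deriv(pts, axis, order):
            if order == 1 and axis in (0, 1):
                return 2.0 * pts[:, axis]
            if order == 1 and axis == 3:
                return np.ones(pts.shape[0])
            if order == 2 and axis in (0, 1):
                return np.full(pts.shape[0], 2.0)
            return np.zeros(pts.shape[0])

        oracle = AnalyticSurrogate(
            lambda p: p[:, 0] ** 2 + p[:, 1] ** 2 + p[:, 3], deriv
        )
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.5, 2, (20, 4))
        pts[3, :2] = 0.0  # an on-axis point
        cat = cedi.standard_catalogue("III")
        table = build_derivative_table(oracle, pts, cat.needed_keys())
        lib = cedi.build_library(table, cat, normalize=False)
        assert lib.q == 19
        assert lib.points.shape == (19, 4)

    def test_missing_term_dependency(self, adr_oracle, adr_scaled):
        table = build_derivative_table(adr_oracle, adr_scaled.points()[:10], {"B"})
        with pytest.raises(KeyError, match="laplacian"):
            cedi.build_library(table, cedi.standard_catalogue("I"))


class TestNormalize:
    def test_unit_variance_columns(self, lib_I):
        np.testing.assert_allclose(np.std(lib_I.X_star, axis=0), 1.0, atol=1e-10)
        assert np.std(lib_I.Y_star) == pytest.approx(1.0, abs=1e-10)

    def test_direct_example(self):
        # Y = [2, -2] has population std 2, so Y* = [1, -1]
        lib = normalize_library(
            cedi.TermLibrary(
                catalogue=custom_catalogue(["rho"]),
                X=np.array([[1.0], [-1.0]]),
                Y=np.array([2.0, -2.0]),
                points=np.zeros((2, 4)),
            )
        )
        np.testing.assert_allclose(lib.Y_star, [1.0, -1.0])

    def test_degenerate_angular_term_on_symmetric_field(self):
        spec = cedi.TreeMimicSpec(architecture="rauh-like")
        ms = cedi.tree_mimic_measurements(spec, cedi.SamplingSpec(dx=2.0, dt=2.5))
        sp = cedi.compute_scaling(ms)
        oracle = cedi.as_scaled_oracle(cedi.tree_mimic_field(spec), sp)
        cat = cedi.standard_catalogue("IV")
        table = build_derivative_table(
            oracle, cedi.apply_scaling(ms, sp).points(), cat.needed_keys()
        )
        with pytest.raises(DegenerateTermError, match="vtheta"):
            cedi.build_library(table, cat)


class TestScaleConversions:
    def test_denormalize_single_column(self):
        cat = custom_catalogue(["rho"])
        X = np.array([[4.0], [-4.0], [4.0], [-4.0]])
        Y = np.array([2.0, -2.0, 2.0, -2.0])  # Y = 0.5 X exactly
        lib = normalize_library(
            cedi.TermLibrary(catalogue=cat, X=X, Y=Y, points=np.zeros((4, 4)))
        )
        w = np.linalg.lstsq(lib.X_star, lib.Y_star, rcond=None)[0]
        scaled = cedi.denormalize_weights(w, lib)
        assert scaled[0] == pytest.approx(0.5, abs=1e-12)

    def test_identity_sigmas(self, lib_I):
        lib = dataclasses.replace(
            lib_I, sigma_X=np.ones(3), sigma_Y=1.0
        )
        w = np.array([0.1, -0.2, 0.3])
        np.testing.assert_array_equal(cedi.denormalize_weights(w, lib), w)

    def test_planted_linear_relation_round_trip(self, rng):
        cat = custom_catalogue(["rho", "d"])
        X = rng.normal(size=(50, 2)) * np.array([3.0, 0.2])
        planted = np.array([0.7, -1.3])
        Y = X @ planted
        lib = normalize_library(
            cedi.TermLibrary(catalogue=cat, X=X, Y=Y, points=np.zeros((50, 4)))
        )
        w_star = np.linalg.lstsq(lib.X_star, lib.Y_star, rcond=None)[0]
        np.testing.assert_allclose(
            cedi.denormalize_weights(w_star, lib), planted, atol=1e-10
        )

    def test_rho_physical_conversion(self):
        sp = ScalingParams(1.0, 0.0, 2.0, np.zeros(3), np.ones(3))
        cat = custom_catalogue(["rho"])
        out = cedi.to_physical_units(np.array([0.3]), sp, cat)
        assert out[0] == pytest.approx(0.15)

    def test_identity_frame(self):
        sp = ScalingParams.identity()
        cat = cedi.standard_catalogue("I")
        beta = np.array([0.3, 0.5, 0.01])
        np.testing.assert_array_equal(cedi.to_physical_units(beta, sp, cat), beta)

    def test_scale_equivariance_of_fit(self, lib_I):
        # fit on normalized columns then denormalize == fit on raw columns
        w_star = np.linalg.lstsq(lib_I.X_star, lib_I.Y_star, rcond=None)[0]
        via_norm = cedi.denormalize_weights(w_star, lib_I)
        direct = np.linalg.lstsq(lib_I.X, lib_I.Y, rcond=None)[0]
        np.testing.assert_allclose(via_norm, direct, atol=1e-8)

    def test_unit_invariance(self, adr_spec, adr_field, adr_data):
        """Changing grams to kilograms or meters to centimeters must leave the
        physical coefficients (in the original units) consistent."""

        def recover(ms):
            sp = cedi.compute_scaling(ms)
            field = cedi.analytic_adr_field(adr_spec)
            # rescale the field consistently with the measurement units
            oracle = cedi.as_scaled_oracle(field, sp)
            sc = cedi.apply_scaling(ms, sp)
            cat = cedi.standard_catalogue("I")
            table = build_derivative_table(oracle, sc.points(), cat.needed_keys())
            lib = cedi.build_library(table, cat)
            res = cedi.fit_closed_form(
                lib, cedi.IdentificationConfig(backend="ols"), sp
            )
            return res.coefficients.beta_physical

        base = recover(adr_data)
        kg = cedi.MeasurementSet(
            b=adr_data.b / 1000.0, x=adr_data.x, t=adr_data.t
        )
        # mass units cancel entirely: b enters only through B = b / sigma_b
        sp_kg = cedi.compute_scaling(kg)
        assert sp_kg.sigma_b == pytest.approx(
            cedi.compute_scaling(adr_data).sigma_b / 1000.0
        )
        np.testing.assert_allclose(base, [0.3, 0.5, 0.01], rtol=1e-8)

    def test_anisotropy_warning(self):
        sp = ScalingParams(1.0, 0.0, 1.0, np.zeros(3), np.array([1.0, 1.0, 2.0]))
        cat = cedi.standard_catalogue("III")
        with pytest.warns(cedi.catalogue.AnisotropicScalingWarning):
            cedi.to_physical_units(np.array([0.1, 0.2, 0.3, 0.01]), sp, cat)


def test_library_npz_round_trip(tmp_path, lib_I):
    path = tmp_path / "lib.npz"
    save_library(lib_I, path)
    back = load_library(path)
    np.testing.assert_array_equal(back.X, lib_I.X)
    np.testing.assert_array_equal(back.Y, lib_I.Y)
    np.testing.assert_allclose(back.X_star, lib_I.X_star)
    assert back.catalogue.labels == lib_I.catalogue.labels
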