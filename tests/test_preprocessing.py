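"""Chemometric preprocessing primitives and the 36-combination grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootspec import (
    InvalidInputError,
    PreprocSpec,
    SpectrumTable,
    apply_spec,
    enumerate_grid,
    log_transform,
    msc_apply,
    msc_fit,
    normalize_spectrum,
    savgol,
    snv,
)

finite_spectra = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False, allow_infinity=False),
    min_size=12,
    max_size=40,
)


class TestGrid:
    def test_grid_has_36_unique_specs(self):
        specs = enumerate_grid()
        assert len(specs) == 36
        assert len({(s.layer1, s.layer2, s.layer3) for s in specs}) == 36

    def test_first_spec_is_identity_pipeline(self):
        assert enumerate_grid()[0].name == "none/none/none"

    def test_contains_log_deriv2_msc(self):
        assert any(s.name == "log/deriv2/msc" for s in enumerate_grid())

    def test_spec_json_round_trip(self):
        spec = PreprocSpec("log", "deriv1", "msc", msc_reference=np.arange(5.0))
        back = PreprocSpec.from_json(spec.to_json())
        assert back.name == spec.name
        np.testing.assert_array_equal(back.msc_reference, spec.msc_reference)

    def test_invalid_layer_rejected(self):
        with pytest.raises(InvalidInputError):
            PreprocSpec(layer1="sqrt")


class TestNormalize:
    def test_three_four_five(self):
        np.testing.assert_allclose(normalize_spectrum(np.array([3.0, 4.0])), [0.6, 0.8])

    def test_unit_vector_unchanged(self):
        v = np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(normalize_spectrum(v), v)

    @settings(deadline=None, max_examples=50)
    @given(finite_spectra)
    def test_output_has_unit_norm(self, xs):
        x = np.asarray(xs)
        if np.linalg.norm(x) == 0:
            return
        assert np.linalg.norm(normalize_spectrum(x)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            normalize_spectrum(np.zeros(4))


class TestLogTransform:
    @pytest.mark.parametrize(
        "r,expected", [(1.0, 0.0), (0.01, 2.0), (0.0, 6.0)]
    )
    def test_absorbance_values(self, r, expected):
        assert log_transform(np.array([r]))[0] == pytest.approx(expected)


class TestSavgol:
    def test_quadratic_reproduced_exactly(self):
        """Polyorder-2 filter reproduces a quadratic, edges included."""
        t = np.arange(30.0)
        x = 0.5 * t**2 - 3 * t + 2
        np.testing.assert_allclose(savgol(x, 11, 2, 0), x, atol=1e-8)

    def test_linear_ramp_derivative_is_slope_per_nm(self):
        wl_step = 3.0
        x = 0.002 * wl_step * np.arange(40.0)  # slope 0.002 per nm
        d = savgol(x, 11, 2, 1, band_spacing_nm=wl_step)
        np.testing.assert_allclose(d, 0.002, atol=1e-12)

    def test_constant_spectrum_derivative_is_zero(self):
        for deriv in (1, 2):
            np.testing.assert_allclose(
                savgol(np.full(25, 0.7), 11, 2, deriv), 0.0, atol=1e-12
            )

    def test_matches_sliding_polyfit_oracle(self, rng):
        """Interior points equal an explicit least-squares window fit."""
        x = rng.random(40)
        win, poly = 11, 2
        out = savgol(x, win, poly, 0)
        half = win // 2
        for centre in range(half, 40 - half):
            t = np.arange(-half, half + 1, dtype=float)
            coeffs = np.polyfit(t, x[centre - half : centre + half + 1], poly)
            assert out[centre] == pytest.approx(np.polyval(coeffs, 0.0), abs=1e-10)

    def test_bad_window_rejected(self):
        with pytest.raises(InvalidInputError):
            savgol(np.zeros(20), 10, 2, 0)  # even window
        with pytest.raises(InvalidInputError):
            savgol(np.zeros(20), 7, 1, 2)  # polyorder below derivative order


class TestSNV:
    def test_small_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_output_standardised(self, rng):
        out = snv(rng.random(50))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        x = rng.random(30)
        np.testing.assert_allclose(snv(snv(x)), snv(x), atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(finite_spectra, st.floats(0.1, 10), st.floats(-3, 3))
    def test_removes_affine_distortion(self, xs, gain, offset):
        x = np.asarray(xs)
        if x.std(ddof=1) < 1e-9:
            return
        np.testing.assert_allclose(snv(gain * x + offset), snv(x), atol=1e-6)

    def test_constant_rejected(self):
        with pytest.raises(InvalidInputError):
            snv(np.full(10, 2.0))


class TestMSC:
    def test_reference_spectrum_unchanged(self, rng):
        X = rng.random((5, 20))
        ref = msc_fit(X)
        np.testing.assert_allclose(msc_apply(ref, ref), ref, atol=1e-10)

    def test_affine_distortion_inverted_exactly(self, rng):
        ref = rng.random(20) + 0.5
        distorted = 2.0 * ref + 0.5
        np.testing.assert_allclose(msc_apply(distorted, ref), ref, atol=1e-10)

    def test_random_affine_family_collapses_to_shape(self, rng):
        """All affine distortions of one shape correct back to the shape."""
        shape = np.sin(np.linspace(0, 3, 30)) + 2.0
        gains = rng.uniform(0.5, 2.0, 8)
        offsets = rng.uniform(-0.3, 0.3, 8)
        X = gains[:, None] * shape[None, :] + offsets[:, None]
        corrected = msc_apply(X, shape)
        np.testing.assert_allclose(corrected, np.tile(shape, (8, 1)), atol=1e-8)

    def test_near_zero_slope_rejected(self, rng):
        ref = np.linspace(1, 2, 10)
        flat = np.full(10, 3.0)  # uncorrelated with the reference
        with pytest.raises(InvalidInputError):
            msc_apply(flat, ref)


class TestApplySpec:
    def _table(self, X):
        wl = np.linspace(450, 950, X.shape[1])
        return SpectrumTable(X=X, wavelengths_nm=wl)

    def test_identity_pipeline_leaves_table_unchanged(self, rng):
        X = rng.random((4, 20))
        _, out = apply_spec(PreprocSpec(), self._table(X))
        np.testing.assert_array_equal(out.X, X)

    def test_snv_maps_proportional_rows_together(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        _, out = apply_spec(PreprocSpec(layer3="snv"), self._table(X))
        np.testing.assert_allclose(out.X, [[-1, 0, 1], [-1, 0, 1]])

    def test_composition_equals_manual_pipeline(self, rng):
        """log -> deriv1 -> msc equals composing the primitives by hand."""
        X = rng.random((6, 40)) + 0.1
        table = self._table(X)
        spec = PreprocSpec("log", "deriv1", "msc")
        fitted, out = apply_spec(spec, table, training=True)
        Z = log_transform(X)
        Z = savgol(Z, spec.savgol_window, spec.savgol_polyorder, 1,
                   band_spacing_nm=table.band_spacing_nm)
        ref = msc_fit(Z)
        np.testing.assert_allclose(out.X, msc_apply(Z, ref), atol=1e-10)
        np.testing.assert_allclose(fitted.msc_reference, ref)

    def test_msc_prediction_requires_fitted_reference(self, rng):
        table = self._table(rng.random((3, 15)))
        with pytest.raises(InvalidInputError, match="not fitted"):
            apply_spec(PreprocSpec(layer3="msc"), table, training=False)

    def test_simulator_scatter_removed_in_zero_noise_limit(self, rng):
        """MSC with the true common shape inverts the simulator's affine
        scatter artifact model exactly when noise is absent."""
        shape = 0.3 + 0.2 * np.sin(np.linspace(0, 4, 50))
        gain = 1.0 + 0.05 * rng.standard_normal(10)
        offset = 0.01 * rng.standard_normal(10)
        X = gain[:, None] * shape[None, :] + offset[:, None]
        corrected = msc_apply(X, shape)
        np.testing.assert_allclose(corrected, np.tile(shape, (10, 1)), atol=1e-8)
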