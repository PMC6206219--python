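"""Pen boundaries, the thick pen transform, and min-max normalization."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.pipeline import Pipeline

import thickpen as tp
from oracles import naive_pen_boundaries, random_curve


class TestPenBoundaries:
    def test_worked_example_on_integer_grid(self):
        curve = tp.SpectralCurve([0, 1, 2, 3, 4], [5, 1, 4, 2, 3])
        band = tp.pen_boundaries(curve, 2.0)
        np.testing.assert_array_equal(band.lower, [1, 1, 2, 2, 3])
        np.testing.assert_array_equal(band.upper, [5, 4, 4, 3, 3])

    def test_constant_curve_collapses_band(self):
        curve = tp.SpectralCurve(np.linspace(0, 10, 30), np.full(30, 3.5))
        band = tp.pen_boundaries(curve, 4.0)
        assert np.all(band.lower == 3.5) and np.all(band.upper == 3.5)

    def test_thickness_below_grid_gap_degenerates_to_curve(self):
        curve = tp.SpectralCurve([0.0, 1.0, 2.0, 3.0], [4.0, 1.0, 3.0, 2.0])
        with pytest.warns(UserWarning, match="smallest grid gap"):
            band = tp.pen_boundaries(curve, 0.5)
        np.testing.assert_array_equal(band.lower, curve.values)
        np.testing.assert_array_equal(band.upper, curve.values)

    def test_monotone_curve_extrema_sit_at_window_ends(self, rng):
        wl = np.cumsum(rng.uniform(0.3, 1.0, 50)) + 300
        y = np.sort(rng.uniform(0, 1, 50))
        band = tp.pen_boundaries(tp.SpectralCurve(wl, y), 7.0)
        np.testing.assert_array_equal(band.lower, y)
        ends = np.searchsorted(wl, wl + 7.0, side="right") - 1
        np.testing.assert_array_equal(band.upper, y[ends])

    def test_band_sandwiches_curve(self, rng):
        curve = random_curve(rng)
        band = tp.pen_boundaries(curve, 5.0)
        assert np.all(band.lower <= curve.values)
        assert np.all(curve.values <= band.upper)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            curve = random_curve(rng)
            tau = float(rng.uniform(0.3, 40.0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # tau may undercut min gap
                band = tp.pen_boundaries(curve, tau)
            lo, hi = naive_pen_boundaries(curve.wavelengths, curve.values, tau)
            np.testing.assert_array_equal(band.lower, lo)
            np.testing.assert_array_equal(band.upper, hi)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.25, 60.0))
    def test_oracle_equivalence_property(self, seed, tau):
        rng = np.random.default_rng(seed)
        curve = random_curve(rng, n=int(rng.integers(5, 80)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            band = tp.pen_boundaries(curve, tau)
        lo, hi = naive_pen_boundaries(curve.wavelengths, curve.values, tau)
        np.testing.assert_array_equal(band.lower, lo)
        np.testing.assert_array_equal(band.upper, hi)

    def test_edge_restrict_drops_truncated_windows(self):
        wl = np.arange(0.0, 10.5, 1.0)
        curve = tp.SpectralCurve(wl, np.sin(wl) + 1.5)
        band = tp.pen_boundaries(curve, 3.0, edge="restrict")
        assert band.wavelengths[-1] <= wl[-1] - 3.0 + 1e-9
        full = tp.pen_boundaries(curve, 3.0, edge="truncate")
        n = band.wavelengths.size
        np.testing.assert_array_equal(band.lower, full.lower[:n])
        np.testing.assert_array_equal(band.upper, full.upper[:n])

    def test_invalid_inputs_raise(self):
        curve = tp.SpectralCurve([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            tp.pen_boundaries(curve, -1.0)
        with pytest.raises(ValueError):
            tp.pen_boundaries(curve, 1.0, edge="reflect")
        with pytest.raises(ValueError):
            tp.SpectralCurve([], [])


class TestThickPenTransform:
    def test_single_thickness_matches_pen_boundaries(self, rng):
        curve = random_curve(rng)
        result = tp.thick_pen_transform(curve, [12.0])
        band = tp.pen_boundaries(curve, 12.0)
        np.testing.assert_array_equal(result.bands[0].lower, band.lower)
        np.testing.assert_array_equal(result.bands[0].upper, band.upper)

    def test_bands_nest_with_increasing_thickness(self, rng):
        curve = tp.simulate_spectrum(tp.SpectrumScenario(seed=3))
        result = tp.thick_pen_transform(curve, tp.STUDY_TAUS)
        assert len(result) == 9
        for thin, thick in zip(result.bands, result.bands[1:]):
            assert np.all(thick.lower <= thin.lower)
            assert np.all(thick.upper >= thin.upper)

    def test_thickness_set_must_increase(self):
        curve = tp.SpectralCurve([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        for bad in ([5.0, 5.0], [5.0, 3.0], [], [0.0, 2.0]):
            with pytest.raises(ValueError):
                tp.thick_pen_transform(curve, bad)

    def test_band_lookup_by_thickness(self, rng):
        curve = random_curve(rng)
        result = tp.thick_pen_transform(curve, [5.0, 10.0])
        assert result.band(10.0).tau == 10.0
        with pytest.raises(KeyError):
            result.band(7.0)


class TestNormalize:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((0.0, 0.5, 1.0), (0.0, 0.5, 1.0)),
            ((2.0, 3.0, 4.0), (0.0, 0.5, 1.0)),
        ],
    )
    def test_affine_map_to_unit_range(self, values, expected):
        curve = tp.SpectralCurve([300.0, 550.0, 800.0], values)
        out = tp.normalize(curve)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_zero_minimum_divides_by_maximum(self, rng):
        y = rng.uniform(0.0, 2.0, 40)
        y[7] = 0.0
        curve = tp.SpectralCurve(np.linspace(300, 800, 40), y)
        out = tp.normalize(curve)
        np.testing.assert_allclose(out.values, y / y.max(), rtol=1e-12)

    def test_bounds_attained(self, rng):
        curve = random_curve(rng)
        out = tp.normalize(curve, window=None)
        assert out.values.min() == 0.0
        assert out.values.max() == 1.0

    def test_window_restricts_before_scaling(self):
        wl = np.linspace(200, 900, 71)
        curve = tp.SpectralCurve(wl, wl.copy())  # increasing ramp
        out = tp.normalize(curve, window=(300.0, 800.0))
        assert out.wavelengths[0] >= 300.0 and out.wavelengths[-1] <= 800.0
        assert out.values.min() == 0.0 and out.values.max() == 1.0

    def test_constant_curve_rejected(self):
        curve = tp.SpectralCurve([300.0, 500.0, 800.0], [2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            tp.normalize(curve)

    def test_positive_affine_rescaling_is_invisible(self, rng):
        curve = random_curve(rng)
        scaled = tp.SpectralCurve(curve.wavelengths, 3.7 * curve.values + 0.9)
        np.testing.assert_allclose(
            tp.normalize(curve, None).values,
            tp.normalize(scaled, None).values,
            rtol=1e-9, atol=1e-12,
        )


class TestSklearnEstimators:
    def test_normalizer_matches_curve_function(self, rng, shared_grid):
        curves = [
            tp.simulate_spectrum(tp.SpectrumScenario(seed=s), grid=shared_grid)
            for s in (1, 2)
        ]
        X = np.stack([c.values for c in curves])
        est = tp.CurveNormalizer(wavelengths=shared_grid, window=(300.0, 800.0))
        out = est.fit_transform(X)
        for row, c in zip(out, curves):
            np.testing.assert_allclose(row, tp.normalize(c).values, rtol=1e-12)

    def test_pen_transform_matches_curve_function(self, rng):
        base = random_curve(rng, n=60)
        wl = base.wavelengths
        X = np.stack([base.values, base.values * 2, base.values + 1])
        est = tp.ThickPenTransform(taus=(5.0, 15.0), wavelengths=wl)
        bands = est.fit(X).transform(X)
        assert bands.shape == (3, 2, 2, wl.size)
        ref = tp.pen_boundaries(tp.SpectralCurve(wl, X[1]), 15.0)
        np.testing.assert_array_equal(bands[1, 1, 0], ref.lower)
        np.testing.assert_array_equal(bands[1, 1, 1], ref.upper)

    def test_estimators_clone_and_compose(self, shared_grid):
        pipe = Pipeline(
            [
                ("norm", tp.CurveNormalizer(wavelengths=shared_grid)),
                ("pens", tp.ThickPenTransform(taus=(20.0, 40.0),
                                              wavelengths=shared_grid)),
            ]
        )
        clone(pipe)  # get_params/set_params round-trip
        X = np.stack(
            [
                tp.simulate_spectrum(
                    tp.SpectrumScenario(seed=s), grid=shared_grid
                ).values
                for s in (5, 6)
            ]
        )
        out = pipe.fit_transform(X)
        assert out.shape == (2, 2, 2, shared_grid.size)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_restrict_edge_gives_common_short_grid(self):
        wl = np.arange(0.0, 50.0)
        X = np.sin(wl)[None, :] + 1.5
        est = tp.ThickPenTransform(taus=(5.0, 10.0), wavelengths=wl, edge="restrict")
        out = est.fit(X).transform(X)
        assert est.output_wavelengths_[-1] <= wl[-1] - 10.0 + 1e-9
        assert out.shape[-1] == est.output_wavelengths_.size
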