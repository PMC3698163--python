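"""Vector normalisation, Savitzky-Golay derivatives, standardisation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import specfinger as sf
from specfinger.exceptions import ConfigError, DegenerateInputError, GridError
from specfinger.preprocess import (
    PreprocessConfig,
    savgol_derivative_set,
    standardize_region,
    vector_normalize,
    vector_normalize_set,
)
from specfinger.spectra import SpectraSet, Spectrum, SpectralRegion, WavenumberGrid


def make_set(X, high=2000.0, step=4.0):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grid = WavenumberGrid(high - step * np.arange(X.shape[1]))
    return SpectraSet(grid, [f"s{i}" for i in range(X.shape[0])],
                      ["unknown"] * X.shape[0], X)


class TestVectorNormalize:
    def test_hand_computed_example(self):
        out = vector_normalize(Spectrum("a", "unknown", [1.0, 2.0, 3.0]))
        np.testing.assert_allclose(
            out.intensities, [-1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)], atol=1e-12
        )

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    def test_unit_norm_zero_mean_postcondition(self, values):
        x = np.asarray(values)
        if np.ptp(x) < 1e-6:
            return
        out = vector_normalize(Spectrum("a", "unknown", x)).intensities
        assert abs(np.linalg.norm(out) - 1.0) < 1e-12
        assert abs(out.mean()) < 1e-12

    def test_constant_spectrum_degenerate(self):
        with pytest.raises(DegenerateInputError, match="constant"):
            vector_normalize(Spectrum("flat", "unknown", [5.0, 5.0, 5.0]))

    def test_idempotent_up_to_recentering(self):
        rng = np.random.default_rng(0)
        s = make_set(rng.standard_normal((4, 30)))
        once = vector_normalize_set(s)
        twice = vector_normalize_set(once)
        np.testing.assert_allclose(once.X, twice.X, atol=1e-12)


def savgol_oracle(y, x, window, polyorder, deriv):
    """Independent oracle: explicit least-squares polynomial fit per
    centred window, differentiated analytically, interior points only."""
    half = window // 2
    out = np.full(y.size, np.nan)
    for i in range(half, y.size - half):
        xs = x[i - half : i + half + 1] - x[i]
        coeffs = np.polyfit(xs, y[i - half : i + half + 1], polyorder)
        p = np.polynomial.Polynomial(coeffs[::-1])
        out[i] = p.deriv(deriv)(0.0)
    return out


class TestSavgolDerivative:
    def test_constant_second_derivative_is_zero(self):
        s = make_set(np.full((1, 50), 3.7))
        out = savgol_derivative_set(s, PreprocessConfig(derivative_order=2))
        np.testing.assert_allclose(out.X, 0.0, atol=1e-10)

    def test_quadratic_reproduced_exactly(self):
        # y = (w - w0)^2 has second derivative 2 everywhere; a cubic fit
        # reproduces a quadratic exactly, so interior points equal the
        # oracle and the analytic value
        s = make_set(np.zeros((1, 60)))
        w = s.grid.values
        y = (w - w[30]) ** 2
        s = s.with_intensities(y[None, :])
        cfg = PreprocessConfig(derivative_order=2)
        out = savgol_derivative_set(s, cfg).X[0]
        oracle = savgol_oracle(y, w, cfg.sg_window, cfg.sg_polyorder, 2)
        interior = slice(4, -4)
        np.testing.assert_allclose(out[interior], oracle[interior], atol=1e-8)
        np.testing.assert_allclose(out[interior], 2.0, atol=1e-8)

    def test_linear_ramp_first_derivative_is_slope(self):
        # slope is with respect to wavenumber, so the descending storage
        # order must not flip the sign
        s = make_set(np.zeros((1, 40)))
        w = s.grid.values
        y = 0.25 * w + 3.0
        s = s.with_intensities(y[None, :])
        cfg = PreprocessConfig(derivative_order=1)
        out = savgol_derivative_set(s, cfg).X[0]
        oracle = savgol_oracle(y, w, cfg.sg_window, cfg.sg_polyorder, 1)
        np.testing.assert_allclose(out[4:-4], oracle[4:-4], atol=1e-10)
        np.testing.assert_allclose(out, 0.25, atol=1e-10)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 60))
        cfg = PreprocessConfig()
        f = lambda y: savgol_derivative_set(make_set(y[None, :]), cfg).X[0]
        np.testing.assert_allclose(
            f(2.0 * a - 0.5 * b), 2.0 * f(a) - 0.5 * f(b), atol=1e-10
        )

    def test_short_spectrum_rejected(self):
        s = make_set(np.ones((1, 5)))
        with pytest.raises(GridError, match="shorter"):
            savgol_derivative_set(s, PreprocessConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(sg_window=8)
        with pytest.raises(ConfigError):
            PreprocessConfig(sg_polyorder=1, derivative_order=2)


class TestStandardize:
    def test_per_spectrum_hand_example(self):
        s = make_set([2.0, 4.0, 6.0])
        out, _ = standardize_region(s, s, PreprocessConfig())
        np.testing.assert_allclose(
            out.X[0], [-np.sqrt(1.5), 0.0, np.sqrt(1.5)], atol=1e-4
        )
        # population variance exactly 1
        assert abs(out.X[0].std() - 1.0) < 1e-12

    def test_cohort_mode_train_columns_centred(self):
        rng = np.random.default_rng(2)
        train = make_set(rng.standard_normal((20, 15)))
        cfg = PreprocessConfig(standardize_mode="per_wavenumber_cohort")
        out, params = standardize_region(train, train, cfg)
        np.testing.assert_allclose(out.X.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.X.std(axis=0), 1.0, atol=1e-10)
        # parameters re-apply exactly
        again = params.apply(train)
        np.testing.assert_array_equal(out.X, again.X)

    def test_constant_column_cohort_mode_degenerate(self):
        X = np.random.default_rng(3).standard_normal((10, 5))
        X[:, 2] = 1.0
        cfg = PreprocessConfig(standardize_mode="per_wavenumber_cohort")
        s = make_set(X)
        with pytest.raises(DegenerateInputError, match="wavenumber"):
            standardize_region(s, s, cfg)

    def test_constant_segment_per_spectrum_degenerate(self):
        X = np.random.default_rng(3).standard_normal((3, 5))
        X[1] = 2.0
        s = make_set(X)
        with pytest.raises(DegenerateInputError, match="s1"):
            standardize_region(s, s, PreprocessConfig())


class TestPreprocessSet:
    def test_feature_count_matches_region_enumeration(self):
        cohort = sf.generate_cohort(
            sf.SyntheticCohortConfig(seed=8, n_positive=3, n_negative=3)
        )
        regions = list(sf.DEFAULT_REGIONS)
        fm = sf.preprocess_set(cohort, regions)
        w = cohort.grid.values
        expected = sum(
            int(np.sum((w >= r.low) & (w <= r.high))) for r in regions
        )
        assert fm.X.shape == (6, expected)

    def test_feature_map_injective_and_complete(self, small_feature_matrix):
        fm = small_feature_matrix
        assert list(fm.feature_map.index) == list(range(fm.X.shape[1]))
        keys = set(zip(fm.feature_map["region_index"], fm.feature_map["wavenumber"]))
        assert len(keys) == fm.X.shape[1]
        # region blocks tile the columns
        cols = sorted(
            i for sl in fm.region_blocks.values() for i in range(sl.start, sl.stop)
        )
        assert cols == list(range(fm.X.shape[1]))

    def test_rowwise_independence_in_per_spectrum_mode(self):
        cohort = sf.generate_cohort(
            sf.SyntheticCohortConfig(seed=8, n_positive=4, n_negative=4)
        )
        full = sf.preprocess_set(cohort, sf.DEFAULT_REGIONS)
        sub = sf.preprocess_set(cohort.subset([1, 3, 6]), sf.DEFAULT_REGIONS)
        np.testing.assert_allclose(full.X[[1, 3, 6]], sub.X, atol=1e-12)
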