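"""Cleaning chain: filter response, projections, smoothing, standardization."""

import numpy as np
import pytest

from boldcaps import SimParams, generate_cohort
from boldcaps.preprocess import (
    NuisanceRegression,
    NuisanceSet,
    PolynomialDetrend,
    TemporalBandpass,
    ZeroVarianceWarning,
    bandpass_filter,
    build_nuisance,
    detrend_poly,
    preprocess_session,
    regress_nuisance,
    smooth_spatial,
    standardize,
)
from boldcaps.simulate import canonical_hrf

from conftest import make_session, series_session

TR = 2.46


def _sinusoid_session(freq_hz, t=197):
    time = np.arange(t) * TR
    return series_session(np.sin(2 * np.pi * freq_hz * time)[:, None]), time


def _fitted_amplitude(series, freq_hz, time):
    """Amplitude of the component at freq_hz, central 60% (edge-safe)."""
    lo, hi = int(0.2 * len(series)), int(0.8 * len(series))
    design = np.stack(
        [np.sin(2 * np.pi * freq_hz * time[lo:hi]), np.cos(2 * np.pi * freq_hz * time[lo:hi])],
        axis=1,
    )
    coef, *_ = np.linalg.lstsq(design, series[lo:hi], rcond=None)
    return float(np.hypot(*coef))


class TestBandpass:
    def test_constant_series_zeroed(self):
        sess = series_session(np.full((197, 1), 7.0))
        out = bandpass_filter(sess)
        assert np.abs(out.masked_timeseries()).max() < 1e-8

    @pytest.mark.parametrize(
        "freq,kind", [(0.05, "pass"), (0.19, "stop")]
    )
    def test_frequency_response(self, freq, kind):
        sess, time = _sinusoid_session(freq)
        out = bandpass_filter(sess).masked_timeseries()[:, 0]
        amp = _fitted_amplitude(out, freq, time)
        if kind == "pass":
            assert amp >= 0.9
        else:
            assert amp <= 0.1

    def test_high_edge_above_nyquist_rejected(self):
        sess = series_session(np.random.default_rng(0).normal(size=(60, 1)))
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(sess, high_hz=0.25)  # Nyquist is 0.2033 Hz

    def test_estimator_validates_band_order(self):
        with pytest.raises(ValueError, match="low_hz"):
            TemporalBandpass(low_hz=0.2, high_hz=0.1, tr_seconds=TR).fit(
                np.zeros((50, 2))
            )


class TestDetrend:
    def test_exact_polynomial_removed(self):
        t = np.linspace(-1, 1, 50)
        sess = series_session((2.0 + 3.0 * t - 1.5 * t**2)[:, None])
        out = detrend_poly(sess, order=2)
        assert np.abs(out.masked_timeseries()).max() < 1e-10

    def test_projection_contracts_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 5))
        sess = series_session(x)
        out = detrend_poly(sess, order=2).masked_timeseries()
        assert (out.var(axis=0) <= x.var(axis=0) + 1e-12).all()

    def test_cubic_residual_matches_least_squares_oracle(self):
        t = np.linspace(-1, 1, 60)
        y = t**3
        design = np.stack([np.ones_like(t), t, t**2], axis=1)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        oracle = y - design @ coef
        out = detrend_poly(series_session(y[:, None]), order=2).masked_timeseries()[:, 0]
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_residual_orthogonal_to_basis(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 3))
        out = PolynomialDetrend(order=2).fit_transform(x)
        t = np.linspace(-1, 1, 60)
        for basis_vec in (np.ones(60), t, t**2):
            inner = np.abs(out.T @ basis_vec)
            assert (inner < 1e-8 * np.linalg.norm(out, axis=0) * np.linalg.norm(basis_vec)).all()

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="order"):
            PolynomialDetrend(order=3).fit(np.zeros((50, 1)))
        with pytest.raises(ValueError, match="frames"):
            PolynomialDetrend(order=2)._basis(3)


class TestNuisance:
    def test_series_equal_to_regressor_vanishes(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=60)
        sess = series_session(g[:, None])
        nuis = NuisanceSet(regressors=g[:, None], names=["global"])
        out = regress_nuisance(sess, nuis).masked_timeseries()
        assert np.abs(out).max() < 1e-10

    def test_orthogonal_series_unchanged_up_to_mean(self):
        t = 64
        x = np.sin(2 * np.pi * 3 * np.arange(t) / t)
        r = np.sin(2 * np.pi * 5 * np.arange(t) / t)  # orthogonal on full cycles
        out = NuisanceRegression(regressors=r[:, None]).fit_transform(x[:, None] + 4.0)
        np.testing.assert_allclose(out[:, 0], x, atol=1e-8)

    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(50, 2))
        R = rng.normal(size=(50, 3))
        design = np.column_stack([np.ones(50), R])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        oracle = y - design @ beta
        out = NuisanceRegression(regressors=R).fit_transform(y)
        np.testing.assert_allclose(out, oracle, atol=1e-8)

    def test_collinearity_error_names_columns(self):
        r = np.arange(20.0)
        R = np.column_stack([r, 2 * r])
        with pytest.raises(ValueError, match="collinear"):
            NuisanceRegression(regressors=R, names=["a", "b"]).fit(
                np.zeros((20, 1))
            )

    def test_all_zero_flagged_regressor_rejected(self):
        with pytest.raises(ValueError, match="all zero"):
            NuisanceSet(regressors=np.zeros((20, 1)), names=["wm"])

    def test_build_nuisance_collects_sources(self, tiny_cohort):
        _, sessions, motion, _ = tiny_cohort
        nuis = build_nuisance(sessions[0], motion_params=motion[0],
                              include=("global", "motion"))
        assert nuis.names == ["global"] + [f"motion_{j}" for j in range(6)]
        assert nuis.regressors.shape == (sessions[0].n_frames, 7)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(5)
        sess = make_session(rng.normal(size=(8, 8, 8, 12)))
        out = smooth_spatial(sess, fwhm_mm=0.0)
        np.testing.assert_array_equal(out.data, sess.data)

    def test_impulse_peak_matches_gaussian_normalization(self):
        data = np.zeros((21, 21, 21, 12))
        data[10, 10, 10, :] = 1.0
        sess = make_session(data, voxel_mm=3.0)
        out = smooth_spatial(sess, fwhm_mm=8.0)
        sigma_vox = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        expected_peak = (2 * np.pi * sigma_vox**2) ** -1.5
        assert out.data[10, 10, 10, 0] == pytest.approx(expected_peak, rel=1e-3)

    def test_constant_volume_preserved_interior(self):
        sess = make_session(np.full((12, 12, 12, 10), 3.3))
        out = smooth_spatial(sess, fwhm_mm=8.0)
        np.testing.assert_allclose(out.data, 3.3, rtol=1e-10)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(6)
        data = np.zeros((20, 20, 20, 10))
        data[6:14, 6:14, 6:14] = rng.normal(2.0, 0.3, size=(8, 8, 8, 10))
        sess = make_session(data)
        out = smooth_spatial(sess, fwhm_mm=8.0)
        before = data.sum(axis=(0, 1, 2))
        after = out.data.sum(axis=(0, 1, 2))
        np.testing.assert_allclose(after, before, rtol=0.01)


class TestStandardize:
    def test_three_point_series(self):
        from boldcaps.preprocess import TemporalStandardize

        out = TemporalStandardize().fit_transform(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_series_zeroed_with_warning(self):
        mat = np.column_stack([np.full(20, 5.0), np.random.default_rng(0).normal(size=20)])
        with pytest.warns(ZeroVarianceWarning, match="1 zero-variance"):
            out = standardize(series_session(mat))
        assert np.all(out.masked_timeseries()[:, 0] == 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        sess = series_session(rng.normal(size=(40, 4)))
        once = standardize(sess)
        twice = standardize(once)
        np.testing.assert_allclose(once.masked_timeseries(), twice.masked_timeseries(),
                                   atol=1e-12)


class TestFullChain:
    def test_mask_respected_through_chain(self, tiny_cohort):
        _, sessions, motion, truth = tiny_cohort
        nuis = build_nuisance(sessions[0], motion_params=motion[0], include=("motion",))
        out = preprocess_session(sessions[0], nuisance=nuis)
        assert np.all(out.data[~out.mask] == 0.0)

    def test_event_frames_track_planted_patterns(self):
        """After the full chain, averaged event frames correlate >= 0.8
        with their ground-truth pattern maps."""
        params = SimParams(
            n_subjects=1, n_conditions=1, n_frames=197,
            k_true=3, spike_rate=0.0, rng_seed=21,
        )
        sessions, motion, truth = generate_cohort(params)
        nuis = build_nuisance(sessions[0], motion_params=motion[0], include=("motion",))
        clean = preprocess_session(sessions[0], nuisance=nuis)
        lag = truth.hrf_peak_lag
        mat = clean.masked_timeseries()
        pats = truth.pattern_matrix()
        for pid in range(params.k_true):
            idx = [f + lag for f, p in truth.event_times[(0, 0)]
                   if p == pid and f + lag < params.n_frames]
            mean_frame = mat[idx].mean(axis=0)
            r = np.corrcoef(mean_frame, pats[pid])[0, 1]
            assert r >= 0.8, f"pattern {pid}: correlation {r:.3f}"
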