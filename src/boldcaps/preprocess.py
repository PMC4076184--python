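"""Temporal/spatial cleaning chain and voxelwise standardization.

The chain reproduces a conventional seed-based connectivity preprocessing
stream: polynomial detrending (linear + quadratic), 0.005-0.1 Hz bandpass,
nuisance regression (global mean, white-matter and CSF ROI means, six
rigid-body motion parameters), 8 mm FWHM spatial smoothing, and per-voxel
demeaning / division by the temporal standard deviation.

Voxelwise stages are scikit-learn transformers on ``(t, n_voxels)``
matrices (frames are samples, voxels are features), so they compose with
:class:`sklearn.pipeline.Pipeline`; the module-level functions wrap them
for :class:`~boldcaps.session.BoldSession` objects and are mask-respecting
(out-of-mask voxels are untouched).  Smoothing operates on the 3D grid and
is function-only.

The stage order (detrend, bandpass, regress, smooth, standardize) avoids
re-introducing filtered-out frequencies through the regressors; it is a
convention of this package, not a property of the method, and each stage
can be called independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.signal
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .session import BoldSession

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ZeroVarianceWarning(UserWarning):
    """Raised when standardization meets constant voxel time series."""


# --------------------------------------------------------------------------
# transformers
# --------------------------------------------------------------------------


class TemporalBandpass(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth bandpass along the time axis.

    A second-order Butterworth (per pass) applied forward-backward
    (``sosfiltfilt``), so the effective magnitude response is the square of
    the single-pass response and the phase is exactly zero — event timing,
    which the point process depends on, is not shifted.

    Parameters
    ----------
    low_hz, high_hz : float
        Band edges; ``0 <= low_hz < high_hz < 1/(2 TR)``.
    tr_seconds : float
        Sampling interval.
    order : int, default 2
        Butterworth order per edge per pass.
    """

    def __init__(self, low_hz: float = 0.005, high_hz: float = 0.1,
                 tr_seconds: float = 2.46, order: int = 2):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.tr_seconds = tr_seconds
        self.order = order

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=10)
        nyq = 0.5 / self.tr_seconds
        if not 0.0 <= self.low_hz < self.high_hz:
            raise ValueError(f"need 0 <= low_hz < high_hz, got ({self.low_hz}, {self.high_hz})")
        if self.high_hz >= nyq:
            raise ValueError(
                f"high_hz={self.high_hz} must be below the Nyquist frequency {nyq:.4f} Hz"
            )
        fs = 1.0 / self.tr_seconds
        if self.low_hz > 0:
            self.sos_ = scipy.signal.butter(
                self.order, [self.low_hz, self.high_hz], btype="band", fs=fs, output="sos"
            )
        else:
            self.sos_ = scipy.signal.butter(
                self.order, self.high_hz, btype="low", fs=fs, output="sos"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "sos_")
        X = check_array(X)
        return scipy.signal.sosfiltfilt(self.sos_, X, axis=0)


class PolynomialDetrend(BaseEstimator, TransformerMixin):
    """Remove per-voxel polynomial trends up to ``order`` (incl. intercept).

    The residual is the orthogonal projection of each time series off the
    polynomial basis, so it is exactly orthogonal to that basis.
    """

    def __init__(self, order: int = 2):
        self.order = order

    def _basis(self, t: int) -> np.ndarray:
        if self.order not in (1, 2):
            raise ValueError(f"order must be 1 or 2, got {self.order}")
        if t <= self.order + 1:
            raise ValueError(f"need more than {self.order + 1} frames, got {t}")
        x = np.linspace(-1.0, 1.0, t)
        cols = [np.ones(t), x] + [x**p for p in range(2, self.order + 1)]
        q, _ = np.linalg.qr(np.stack(cols, axis=1))
        return q

    def fit(self, X, y=None):
        X = check_array(X)
        self.basis_q_ = self._basis(X.shape[0])
        return self

    def transform(self, X):
        check_is_fitted(self, "basis_q_")
        X = check_array(X)
        if X.shape[0] != self.basis_q_.shape[0]:
            raise ValueError("length mismatch with fitted basis")
        return X - self.basis_q_ @ (self.basis_q_.T @ X)


class NuisanceRegression(BaseEstimator, TransformerMixin):
    """Project out nuisance regressors (plus an always-included intercept).

    Parameters
    ----------
    regressors : ndarray, shape (t, r)
    names : sequence of str, optional
        Used in the collinearity error message.
    """

    def __init__(self, regressors=None, names=None):
        self.regressors = regressors
        self.names = names

    def fit(self, X, y=None):
        X = check_array(X)
        t = X.shape[0]
        R = np.asarray(self.regressors, dtype=np.float64)
        if R.ndim == 1:
            R = R[:, None]
        if R.shape[0] != t:
            raise ValueError(f"regressors have {R.shape[0]} rows, data has {t} frames")
        if R.shape[1] > t - 2:
            raise ValueError("too many regressors for the number of frames")
        names = list(self.names) if self.names is not None else [
            f"reg{i}" for i in range(R.shape[1])
        ]
        design = np.column_stack([np.ones(t), R])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            _, r, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
            tol = np.abs(r[0, 0]) * max(design.shape) * np.finfo(float).eps
            bad = sorted(piv[np.abs(np.diag(r)) <= tol])
            labels = ["intercept"] + names
            raise ValueError(
                "collinear nuisance design; offending columns: "
                + ", ".join(labels[i] for i in bad)
            )
        self.design_ = design
        self.design_pinv_ = np.linalg.pinv(design)
        self.names_ = names
        return self

    def transform(self, X):
        check_is_fitted(self, "design_")
        X = check_array(X)
        if X.shape[0] != self.design_.shape[0]:
            raise ValueError("length mismatch with fitted design")
        return X - self.design_ @ (self.design_pinv_ @ X)


class TemporalStandardize(BaseEstimator, TransformerMixin):
    """Demean each voxel and divide by its temporal SD (sample SD, ddof 1).

    Constant series are set to zero and counted in ``n_zero_variance_``
    with a :class:`ZeroVarianceWarning`; they never produce NaN.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=self.ddof)
        self.n_zero_variance_ = int((self.sd_ == 0).sum())
        return self

    def transform(self, X):
        check_is_fitted(self, "sd_")
        X = check_array(X)
        if self.n_zero_variance_:
            warnings.warn(
                f"{self.n_zero_variance_} zero-variance voxel(s) set to 0",
                ZeroVarianceWarning,
                stacklevel=2,
            )
        sd = np.where(self.sd_ == 0, 1.0, self.sd_)
        out = (X - self.mean_) / sd
        out[:, self.sd_ == 0] = 0.0
        return out


# --------------------------------------------------------------------------
# nuisance set
# --------------------------------------------------------------------------


@dataclass
class NuisanceSet:
    """Named nuisance regressors with per-regressor include flags."""

    regressors: np.ndarray  # (t, r)
    names: list[str]
    include_flags: list[bool] = None

    def __post_init__(self):
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=np.float64))
        if self.include_flags is None:
            self.include_flags = [True] * self.regressors.shape[1]
        if len(self.names) != self.regressors.shape[1]:
            raise ValueError("one name per regressor column required")
        if len(self.include_flags) != self.regressors.shape[1]:
            raise ValueError("one include flag per regressor column required")
        for j, (name, on) in enumerate(zip(self.names, self.include_flags)):
            if on and not np.any(self.regressors[:, j]):
                raise ValueError(f"included regressor '{name}' is all zero")

    def active(self) -> tuple[np.ndarray, list[str]]:
        flags = np.asarray(self.include_flags, dtype=bool)
        return self.regressors[:, flags], [n for n, f in zip(self.names, flags) if f]


def build_nuisance(
    session: BoldSession,
    motion_params: np.ndarray | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    include: tuple[str, ...] = ("global", "wm", "csf", "motion"),
) -> NuisanceSet:
    """Assemble the standard nuisance set from a session.

    ``wm_mask`` / ``csf_mask`` are stand-in ROI masks (no tissue
    segmentation exists on synthetic grids); omitted sources are skipped.
    """
    cols, names = [], []
    if "global" in include:
        cols.append(session.data[session.mask].mean(axis=0))
        names.append("global")
    if "wm" in include and wm_mask is not None:
        cols.append(session.data[np.asarray(wm_mask, bool)].mean(axis=0))
        names.append("wm")
    if "csf" in include and csf_mask is not None:
        cols.append(session.data[np.asarray(csf_mask, bool)].mean(axis=0))
        names.append("csf")
    if "motion" in include and motion_params is not None:
        mp = np.asarray(motion_params, dtype=np.float64)
        for j in range(mp.shape[1]):
            cols.append(mp[:, j])
            names.append(f"motion_{j}")
    if not cols:
        raise ValueError("no nuisance regressors selected")
    return NuisanceSet(regressors=np.column_stack(cols), names=names)


# --------------------------------------------------------------------------
# session-level operations
# --------------------------------------------------------------------------


def bandpass_filter(session: BoldSession, low_hz: float = 0.005, high_hz: float = 0.1,
                    order: int = 2) -> BoldSession:
    tf = TemporalBandpass(low_hz=low_hz, high_hz=high_hz,
                          tr_seconds=session.tr_seconds, order=order)
    return session.with_masked_timeseries(tf.fit_transform(session.masked_timeseries()))


def detrend_poly(session: BoldSession, order: int = 2) -> BoldSession:
    return session.with_masked_timeseries(
        PolynomialDetrend(order=order).fit_transform(session.masked_timeseries())
    )


def regress_nuisance(session: BoldSession, nuisance: NuisanceSet) -> BoldSession:
    R, names = nuisance.active()
    return session.with_masked_timeseries(
        NuisanceRegression(regressors=R, names=names).fit_transform(
            session.masked_timeseries()
        )
    )


def smooth_spatial(session: BoldSession, fwhm_mm: float = 8.0) -> BoldSession:
    """3D Gaussian smoothing per frame, reflective boundaries.

    ``sigma = FWHM / (2 sqrt(2 ln 2))`` per axis, converted to voxel units
    through the affine's voxel sizes.  Out-of-mask voxels are re-zeroed so
    the stage stays mask-respecting.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return session.with_data(session.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / session.voxel_sizes_mm
    out = np.empty_like(session.data)
    for i in range(session.n_frames):
        out[..., i] = gaussian_filter(session.data[..., i], sigma=sigma_vox, mode="reflect")
    out[~session.mask] = session.data[~session.mask]
    return session.with_data(out)


def standardize(session: BoldSession) -> BoldSession:
    mat = session.masked_timeseries()
    return session.with_masked_timeseries(TemporalStandardize().fit_transform(mat))


def preprocess_session(
    session: BoldSession,
    nuisance: NuisanceSet | None = None,
    detrend_order: int = 2,
    low_hz: float = 0.005,
    high_hz: float = 0.1,
    fwhm_mm: float = 8.0,
) -> BoldSession:
    """Full cleaning chain: detrend -> bandpass -> regress -> smooth -> standardize."""
    out = detrend_poly(session, order=detrend_order)
    out = bandpass_filter(out, low_hz=low_hz, high_hz=high_hz)
    if nuisance is not None:
        out = regress_nuisance(out, nuisance)
    out = smooth_spatial(out, fwhm_mm=fwhm_mm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ZeroVarianceWarning)
        out = standardize(out)
    return out
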