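import numpy as np
import pytest

from boldcaps import SimParams, generate_cohort
from boldcaps.session import BoldSession


def make_session(data, tr_seconds=2.46, mask=None, voxel_mm=3.0, **kw):
    """Session from a raw (x, y, z, t) array with a scaled-identity affine."""
    data = np.asarray(data, dtype=np.float64)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return BoldSession(data=data, affine=affine, mask=mask, tr_seconds=tr_seconds, **kw)


def series_session(series_matrix, tr_seconds=2.46):
    """Session whose in-mask voxels carry the given (t, n_voxels) series."""
    series_matrix = np.atleast_2d(np.asarray(series_matrix, dtype=np.float64))
    if series_matrix.shape[0] < series_matrix.shape[1]:
        pass
    t, v = series_matrix.shape
    data = np.zeros((v, 1, 1, t))
    data[:, 0, 0, :] = series_matrix.T
    return make_session(data, tr_seconds=tr_seconds)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted cohort shared by read-only tests (2 x 2 x 60 frames)."""
    params = SimParams(
        n_subjects=2,
        n_conditions=2,
        n_frames=60,
        grid_dims=(14, 16, 14),
        k_true=3,
        rng_seed=7,
    )
    sessions, motion, truth = generate_cohort(params)
    return params, sessions, motion, truth
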