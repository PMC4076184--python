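"""Spatio-temporal point process: seed extraction and frame selection.

The analysis reduces a preprocessed session to the discrete set of frames
at which the seed signal exceeds an amplitude threshold (default +1 SD —
for a Gaussian series roughly the top 15% of time points, 1 - Phi(1) =
15.87%).  The whole-brain maps at those frames are the raw material for
CAP clustering.  A negative-sign mode selects troughs (seed < -threshold)
for the trough-pattern comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .session import BoldSession

#: Default seed center: posterior cingulate cortex in MNI mm.  The y
#: coordinate is negative (posterior); sources occasionally print it
#: without the sign, so the value is configurable and logged.
DEFAULT_PCC_CENTER_MM = (0.0, -53.0, 26.0)


class EmptyPointProcessWarning(UserWarning):
    """No frame crossed the threshold; downstream stages must handle this."""


@dataclass
class SeedSpec:
    """An axis-aligned cube seed in mm space."""

    center_mm: tuple[float, float, float] = DEFAULT_PCC_CENTER_MM
    edge_mm: float = 6.0
    space_tag: str = "mni"

    def __post_init__(self):
        if self.edge_mm < 0:
            raise ValueError("edge_mm must be non-negative")


@dataclass
class PointProcess:
    """Supra-threshold seed events and their whole-brain frames."""

    event_indices: np.ndarray  # (n_events,) strictly increasing
    seed_values: np.ndarray  # (n_events,) in SD units
    frames: np.ndarray  # (n_events, n_in_mask_voxels) standardized maps
    threshold_sd: float
    sign: str
    n_frames_total: int = 0
    n_frames_kept: int = 0

    @property
    def n_events(self) -> int:
        return int(self.event_indices.shape[0])

    @property
    def selected_fraction(self) -> float:
        """Events / total frames (before censoring)."""
        return self.n_events / self.n_frames_total if self.n_frames_total else 0.0

    @property
    def selected_fraction_of_kept(self) -> float:
        """Events / frames surviving censoring."""
        return self.n_events / self.n_frames_kept if self.n_frames_kept else 0.0


def resolve_seed(seed: SeedSpec, session: BoldSession) -> np.ndarray:
    """Indices (into the in-mask voxel columns) of seed-cube voxels.

    A voxel belongs to the seed when its center lies within the *closed*
    axis-aligned cube of edge ``edge_mm`` around ``center_mm``; with 3 mm
    voxels and a 6 mm edge centered on a voxel corner this resolves to the
    canonical 2x2x2 block.  ``edge_mm = 0`` degenerates to the single voxel
    containing the center.
    """
    center = np.asarray(seed.center_mm, dtype=np.float64)
    if seed.space_tag == "mni":
        logging.getLogger("boldcaps").info(
            "resolving MNI seed at %s mm (y is negative for posterior seeds; "
            "override via SeedSpec.center_mm if needed)", tuple(center)
        )
    inv = np.linalg.inv(session.affine)
    if seed.edge_mm == 0:
        vox = np.round(inv @ np.array([*center, 1.0]))[:3].astype(int)
        if (vox < 0).any() or (vox >= np.array(session.grid_dims)).any() or not session.mask[
            tuple(vox)
        ]:
            raise ValueError(f"seed center {tuple(center)} falls outside the brain mask")
        flat = np.ravel_multi_index(tuple(vox), session.grid_dims)
        col = np.searchsorted(np.flatnonzero(session.mask.ravel()), flat)
        return np.array([col])

    mask_flat = np.flatnonzero(session.mask.ravel())
    ijk = np.stack(np.unravel_index(mask_flat, session.grid_dims), axis=1).astype(np.float64)
    homog = np.column_stack([ijk, np.ones(len(ijk))])
    centers_mm = homog @ session.affine.T
    inside = (np.abs(centers_mm[:, :3] - center) <= seed.edge_mm / 2.0 + 1e-9).all(axis=1)
    cols = np.flatnonzero(inside)
    if cols.size == 0:
        raise ValueError(
            f"seed cube at {tuple(center)} (edge {seed.edge_mm} mm) contains no "
            "in-mask voxel centers"
        )
    return cols


def seed_timecourse(session: BoldSession, seed_cols: np.ndarray) -> np.ndarray:
    """Mean over seed voxels, re-standardized to mean 0 / SD 1 (ddof 1)."""
    mat = session.masked_timeseries()
    series = mat[:, np.asarray(seed_cols, int)].mean(axis=1)
    sd = series.std(ddof=1)
    if sd == 0:
        raise ValueError("seed time course has zero variance")
    return (series - series.mean()) / sd


def select_frames(
    session: BoldSession,
    seed_series: np.ndarray,
    threshold_sd: float = 1.0,
    sign: str = "positive",
    keep_mask: np.ndarray | None = None,
) -> PointProcess:
    """Select frames where the seed crosses the threshold (strict ``>``).

    ``sign="positive"`` keeps frames with seed value > threshold;
    ``sign="negative"`` keeps seed value < -threshold.  Frames censored by
    ``keep_mask`` are excluded before selection.  Returned frames are the
    standardized in-mask maps at the selected time points.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if sign not in ("positive", "negative"):
        raise ValueError(f"sign must be 'positive' or 'negative', got {sign!r}")
    seed_series = np.asarray(seed_series, dtype=np.float64)
    t = session.n_frames
    if seed_series.shape[0] != t:
        raise ValueError("seed series length does not match session frames")
    if keep_mask is None:
        keep_mask = np.ones(t, dtype=bool)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    if keep_mask.shape[0] != t:
        raise ValueError("keep_mask length does not match session frames")

    if sign == "positive":
        crossing = seed_series > threshold_sd
    else:
        crossing = seed_series < -threshold_sd
    sel = np.flatnonzero(crossing & keep_mask)
    if sel.size == 0:
        warnings.warn(
            "no frames crossed the seed threshold; point process is empty",
            EmptyPointProcessWarning,
            stacklevel=2,
        )
    mat = session.masked_timeseries()
    return PointProcess(
        event_indices=sel,
        seed_values=seed_series[sel],
        frames=mat[sel],
        threshold_sd=float(threshold_sd),
        sign=sign,
        n_frames_total=t,
        n_frames_kept=int(keep_mask.sum()),
    )


def extract_point_process(
    session: BoldSession,
    seed: SeedSpec,
    threshold_sd: float = 1.0,
    sign: str = "positive",
    keep_mask: np.ndarray | None = None,
) -> PointProcess:
    """Convenience chain: resolve seed -> seed time course -> select frames."""
    cols = resolve_seed(seed, session)
    series = seed_timecourse(session, cols)
    return select_frames(session, series, threshold_sd=threshold_sd, sign=sign,
                         keep_mask=keep_mask)
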