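"""Framewise displacement, DVARS and frame censoring.

FD follows the Power convention: the sum of absolute frame-to-frame
differentials of the three translations (mm) and the three rotations
converted to arc length on a sphere of ``head_radius_mm`` (default 50 mm).
DVARS is the RMS over in-mask voxels of the frame-to-frame intensity
difference, expressed as percent of the session's in-mask grand-mean
intensity — computed on data *before* voxelwise standardization, since
"% BOLD" is meaningless after per-voxel z-scoring.  Both series are zero
at frame 0 by convention (no predecessor).

The default censoring rule flags a frame only when FD and DVARS both
exceed their thresholds (0.5 mm, 0.5 %); the either-exceeds variant from
the motion-scrubbing literature is available as ``rule="or"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .session import BoldSession

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESH_MM = 0.5
DEFAULT_DVARS_THRESH_PCT = 0.5


def compute_fd(params: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement (mm) from a (t, 6) rigid-body series.

    Columns 0-2 are translations in mm, columns 3-5 rotations in radians;
    rotation differentials are converted to arc length via the head radius.
    ``fd[0] = 0``.
    """
    params = np.asarray(params, dtype=np.float64)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"motion params must have shape (t, 6), got {params.shape}")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(params, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def compute_dvars(session: BoldSession) -> np.ndarray:
    """DVARS (% of grand-mean in-mask intensity); ``dvars[0] = 0``."""
    mat = session.masked_timeseries()  # (t, V)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    grand_mean = mat.mean()
    if grand_mean <= 0:
        raise ValueError(
            "non-positive grand-mean intensity; DVARS must be computed on "
            "unnormalized data"
        )
    rms = np.sqrt((np.diff(mat, axis=0) ** 2).mean(axis=1))
    return np.concatenate([[0.0], 100.0 * rms / grand_mean])


def censor_frames(
    fd: np.ndarray,
    dvars: np.ndarray,
    fd_thresh: float = DEFAULT_FD_THRESH_MM,
    dvars_thresh: float = DEFAULT_DVARS_THRESH_PCT,
    rule: str = "and",
) -> np.ndarray:
    """Keep mask from the joint FD/DVARS rule.

    ``rule="and"`` (default): a frame is censored iff FD and DVARS are both
    above threshold.  ``rule="or"``: censored if either exceeds.
    """
    fd = np.asarray(fd, dtype=np.float64)
    dvars = np.asarray(dvars, dtype=np.float64)
    if fd.shape != dvars.shape:
        raise ValueError(f"fd and dvars lengths differ: {fd.shape} vs {dvars.shape}")
    if rule == "and":
        bad = (fd > fd_thresh) & (dvars > dvars_thresh)
    elif rule == "or":
        bad = (fd > fd_thresh) | (dvars > dvars_thresh)
    else:
        raise ValueError(f"rule must be 'and' or 'or', got {rule!r}")
    return ~bad


@dataclass
class MotionTrace:
    """Per-session motion series with derived FD/DVARS and keep mask."""

    params: np.ndarray  # (t, 6)
    fd: np.ndarray
    dvars: np.ndarray
    keep_mask: np.ndarray

    @property
    def censored_fraction(self) -> float:
        return float(1.0 - self.keep_mask.mean())

    @classmethod
    def from_session(
        cls,
        params: np.ndarray,
        session: BoldSession,
        head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
        fd_thresh: float = DEFAULT_FD_THRESH_MM,
        dvars_thresh: float = DEFAULT_DVARS_THRESH_PCT,
        rule: str = "and",
    ) -> "MotionTrace":
        fd = compute_fd(params, head_radius_mm=head_radius_mm)
        dvars = compute_dvars(session)
        if fd.shape[0] != session.n_frames:
            raise ValueError("motion series length does not match session frames")
        keep = censor_frames(fd, dvars, fd_thresh=fd_thresh, dvars_thresh=dvars_thresh, rule=rule)
        return cls(params=np.asarray(params, float), fd=fd, dvars=dvars, keep_mask=keep)

    def to_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.fd.shape[0]),
                "fd_mm": self.fd,
                "dvars_pct": self.dvars,
                "kept": self.keep_mask.astype(int),
            }
        )

    def save_report(self, path: str | Path) -> None:
        self.to_report().to_csv(path, sep="\t", index=False)
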