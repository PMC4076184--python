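"""Second-level inference on CAPs across subjects and conditions.

Subjects are random effects: the unit of analysis is the per-subject,
per-condition, per-CAP mean map.  Two tests are provided, both one-sided:

* **condition significance** — voxelwise one-sample t across subjects
  against zero within one condition (areas co-activated with the seed);
* **linear consciousness contrast** — per subject, the weighted sum of the
  four condition maps with zero-sum weights (default ``[1.5, -0.5, -1.5,
  0.5]`` over wakefulness, sedation, unconsciousness, recovery; recovery
  is down-weighted relative to wakefulness because residual sedative
  plasma levels linger), followed by a one-sample one-sided t of the
  within-subject contrast values against zero.  Collapsing to a
  within-subject contrast sidesteps the sphericity assumptions a
  repeated-measures ANOVA would need.

Multiple comparisons are controlled with Benjamini-Hochberg FDR.
Zero-variance voxels return a documented sentinel (infinite t; p = 0 for a
positive mean, 1 otherwise) rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .session import BoldSession

DEFAULT_CONTRAST_WEIGHTS = (1.5, -0.5, -1.5, 0.5)  # W, S, U, R


@dataclass
class ContrastResult:
    """Voxelwise one-sided test with FDR-thresholded significance mask."""

    weights: np.ndarray
    t_map: np.ndarray
    p_map: np.ndarray
    q_threshold: float
    sig_mask: np.ndarray
    n_subjects: int = 0

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask.sum())


def one_sample_t_one_sided(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t of ``data`` (n_subjects, n_voxels) against 0.

    One-sided (greater-than-zero).  Zero-variance voxels: t = +/-inf with
    p = 0 / 1 by the sign of the mean; an all-zero voxel gives t = 0,
    p = 0.5.
    """
    data = np.asarray(data, dtype=np.float64)
    n = data.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    p = np.full_like(mean, 0.5)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = scipy.stats.t.sf(t[ok], df=n - 1)
    degen = ~ok
    t[degen & (mean > 0)] = np.inf
    p[degen & (mean > 0)] = 0.0
    t[degen & (mean < 0)] = -np.inf
    p[degen & (mean < 0)] = 1.0
    return t, p


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def condition_significance(maps: np.ndarray, q: float = 0.05) -> ContrastResult:
    """Areas co-activated with the seed in one condition, one CAP.

    Parameters
    ----------
    maps : ndarray (n_subjects, n_voxels)
        Per-subject mean maps of the frames assigned to this CAP.
    q : float
        FDR level.
    """
    maps = np.asarray(maps, dtype=np.float64)
    t, p = one_sample_t_one_sided(maps)
    return ContrastResult(
        weights=np.array([1.0]),
        t_map=t,
        p_map=p,
        q_threshold=q,
        sig_mask=fdr_bh(p, q=q),
        n_subjects=maps.shape[0],
    )


def linear_consciousness_contrast(
    maps: np.ndarray,
    weights: tuple | np.ndarray = DEFAULT_CONTRAST_WEIGHTS,
    q: float = 0.05,
) -> ContrastResult:
    """One-sided linear contrast over conditions, subjects as random effects.

    Parameters
    ----------
    maps : ndarray (n_subjects, n_conditions, n_voxels)
        Rows with any NaN (a subject missing a condition cell) are
        excluded pairwise; at least 3 complete subjects are required.
    weights : sequence, length n_conditions, summing to zero.
    """
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim != 3:
        raise ValueError("maps must be (n_subjects, n_conditions, n_voxels)")
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape[0] != maps.shape[1]:
        raise ValueError(
            f"{weights.shape[0]} weights for {maps.shape[1]} conditions"
        )
    if abs(weights.sum()) > 1e-9:
        raise ValueError(f"contrast weights must sum to 0, got {weights.sum()}")
    complete = ~np.isnan(maps).any(axis=(1, 2))
    maps = maps[complete]
    contrasts = np.tensordot(maps, weights, axes=([1], [0]))  # (n_subjects, n_voxels)
    t, p = one_sample_t_one_sided(contrasts)
    return ContrastResult(
        weights=weights,
        t_map=t,
        p_map=p,
        q_threshold=q,
        sig_mask=fdr_bh(p, q=q),
        n_subjects=int(complete.sum()),
    )


# --------------------------------------------------------------------------
# subject-level map assembly
# --------------------------------------------------------------------------


def subject_cap_maps(
    records: list[dict], k: int, subjects: list[str], conditions: list[str]
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble (n_subjects, n_conditions, k, n_voxels) mean maps.

    ``records`` entries carry ``subject_id``, ``condition_label``,
    ``frames`` (n_events, n_voxels) and ``labels`` (n_events,).  Cells with
    no contributing frames are NaN; the returned table reports per-cell
    frame counts so empty cells can be audited before exclusion.
    """
    if not records:
        raise ValueError("no records supplied")
    n_vox = records[0]["frames"].shape[1]
    out = np.full((len(subjects), len(conditions), k, n_vox), np.nan)
    counts = []
    for rec in records:
        s = subjects.index(rec["subject_id"])
        c = conditions.index(rec["condition_label"])
        frames = np.asarray(rec["frames"], float)
        labels = np.asarray(rec["labels"], int)
        for j in range(k):
            sel = labels == j
            counts.append(
                {
                    "subject_id": rec["subject_id"],
                    "condition_label": rec["condition_label"],
                    "cap_index": j,
                    "n_frames_contributing": int(sel.sum()),
                }
            )
            if sel.any():
                out[s, c, j] = frames[sel].mean(axis=0)
    return out, pd.DataFrame(counts)


# --------------------------------------------------------------------------
# baselines
# --------------------------------------------------------------------------


def seed_correlation_map(session: BoldSession, seed_cols: np.ndarray) -> np.ndarray:
    """Pearson correlation of every in-mask voxel with the seed mean series."""
    from .events import seed_timecourse

    mat = session.masked_timeseries()
    seed = seed_timecourse(session, seed_cols)
    mc = mat - mat.mean(axis=0)
    sd = mc.std(axis=0)
    seed_c = seed - seed.mean()
    num = (mc * seed_c[:, None]).mean(axis=0)
    denom = sd * seed_c.std()
    out = np.zeros(mat.shape[1])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def sliding_window_maps(
    session: BoldSession,
    seed_cols: np.ndarray,
    window_frames: int,
    step: int = 1,
) -> np.ndarray:
    """Per-window seed-correlation maps, a dynamic-connectivity baseline.

    Returns ``(n_windows, n_voxels)`` with ``n_windows = floor((t -
    window)/step) + 1``; each row can be fed to the same clustering
    machinery as point-process frames.
    """
    t = session.n_frames
    if window_frames < 3:
        raise ValueError("window_frames must be >= 3")
    if window_frames > t:
        raise ValueError(f"window of {window_frames} frames exceeds series length {t}")
    if step < 1:
        raise ValueError("step must be >= 1")
    mat = session.masked_timeseries()
    seed = mat[:, np.asarray(seed_cols, int)].mean(axis=1)
    starts = range(0, t - window_frames + 1, step)
    maps = []
    for s0 in starts:
        w = slice(s0, s0 + window_frames)
        x = mat[w] - mat[w].mean(axis=0)
        y = seed[w] - seed[w].mean()
        denom = x.std(axis=0) * y.std()
        row = np.zeros(mat.shape[1])
        ok = denom > 0
        row[ok] = (x * y[:, None]).mean(axis=0)[ok] / denom[ok]
        maps.append(row)
    return np.asarray(maps)


def peak_table(
    result: ContrastResult,
    mask: np.ndarray,
    affine: np.ndarray,
    top: int = 10,
) -> pd.DataFrame:
    """Peak-voxel table of the significant map (mm coordinates, t, p)."""
    mask = np.asarray(mask, bool)
    ijk = np.stack(np.unravel_index(np.flatnonzero(mask.ravel()), mask.shape), axis=1)
    sig = np.flatnonzero(result.sig_mask)
    order = sig[np.argsort(result.t_map[sig])[::-1]][:top]
    rows = []
    for col in order:
        mm = np.asarray(affine) @ np.array([*ijk[col], 1.0])
        rows.append(
            {
                "x_mm": mm[0],
                "y_mm": mm[1],
                "z_mm": mm[2],
                "t": result.t_map[col],
                "p": result.p_map[col],
            }
        )
    return pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "t", "p"])
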