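"""Synthetic multi-subject, multi-condition BOLD cohorts with planted CAPs.

The generator emulates the acquisition the analysis targets: a cohort of
subjects scanned in four clinical states (wakefulness, sedation,
unconsciousness, recovery), where supra-threshold peaks of a seed region
co-occur with a small set of distinct whole-brain spatial patterns whose
amplitudes are attenuated condition by condition.  Each session is

    data = baseline + amplitude * sum_j gain[cond, j] * pattern_j(x) * (e_j * h)(t)
           + drift(x, t) + noise,

where ``e_j`` is a Bernoulli event train for pattern ``j``, ``h`` the
canonical double-gamma hemodynamic response sampled at the TR and
renormalized to unit peak, and drift is a per-voxel linear + quadratic
trend.  The seed cube carries unit amplitude in every pattern, so every
event raises the seed regardless of which pattern fired.  Motion traces
carry small jitter plus planted spikes: a sustained translation offset (a
framewise-displacement spike at the onset frame only) paired with a
one-frame global intensity blip (a DVARS spike), so the joint FD & DVARS
censoring rule flags exactly the planted frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from nilearn.glm.first_level import glover_hrf
from scipy.ndimage import gaussian_filter

from .session import BoldSession, save_motion_params, save_pattern_maps

DEFAULT_CONDITIONS = ("wakefulness", "sedation", "unconsciousness", "recovery")


def canonical_hrf(tr_seconds: float, time_length_s: float = 32.0) -> np.ndarray:
    """Double-gamma hemodynamic response sampled at the TR, unit peak."""
    h = glover_hrf(tr_seconds, oversampling=1, time_length=time_length_s)
    return h / h.max()


@dataclass
class SimParams:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the target acquisition: 18 subjects x 4 states x 197
    volumes at TR = 2.46 s on a 3 mm grid, with an event rate chosen so the
    +1 SD seed threshold selects roughly 15% of frames.
    """

    n_subjects: int = 18
    n_conditions: int = 4
    n_frames: int = 197
    tr_seconds: float = 2.46
    grid_dims: tuple[int, int, int] = (20, 24, 20)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    k_true: int = 8
    event_rate: float = 0.15
    rng_seed: int = 0
    # signal scale (BOLD a.u.; baseline 1000 makes 1 a.u. = 0.1% BOLD)
    amplitude: float = 12.0
    baseline: float = 1000.0
    noise_sd: float = 2.5
    noise_spatial_frac: float = 0.7
    noise_spatial_sigma_vox: float = 2.0
    ar1_rho: float = 0.0
    drift_scale: float = 2.0
    # planted pattern geometry
    pattern_sigma_vox: float = 2.2
    pattern_power: float = 0.4
    # motion model
    spike_rate: float = 0.03
    spike_translation_mm: float = 1.0
    spike_intensity_au: float = 10.0
    jitter_translation_mm: float = 0.02
    jitter_rotation_rad: float = 4e-4

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise ValueError("n_frames must be >= 10")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if not 0.0 < self.event_rate < 1.0:
            raise ValueError("event_rate must be in (0, 1)")
        if self.n_subjects < 1 or self.n_conditions < 1:
            raise ValueError("n_subjects and n_conditions must be >= 1")
        if self.noise_sd < 0 or self.amplitude < 0:
            raise ValueError("noise_sd and amplitude must be non-negative")
        if not 0.0 <= self.spike_rate < 1.0:
            raise ValueError("spike_rate must be in [0, 1)")
        if not 0.0 <= self.noise_spatial_frac <= 1.0:
            raise ValueError("noise_spatial_frac must be in [0, 1]")
        if self.pattern_power <= 0:
            raise ValueError("pattern_power must be positive")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    patterns: np.ndarray  # (k_true, x, y, z)
    event_times: dict  # (subject_idx, condition_idx) -> list[(frame, pattern_id)]
    condition_gains: np.ndarray  # (n_conditions, k_true)
    noise_sd: float
    drift_coeffs: dict  # (subject_idx, condition_idx) -> (n_mask_voxels, 2)
    motion_spike_frames: dict  # (subject_idx, condition_idx) -> list[int]
    mask: np.ndarray = None
    affine: np.ndarray = None
    seed_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed_edge_mm: float = 6.0
    condition_labels: tuple = DEFAULT_CONDITIONS
    hrf_peak_lag: int = 0
    rng_seed: int = 0

    def pattern_matrix(self) -> np.ndarray:
        """Planted patterns as a (k_true, n_mask_voxels) matrix."""
        return self.patterns[:, self.mask]


def _ellipsoid_mask(grid_dims: tuple[int, int, int]) -> np.ndarray:
    """Brain-like ellipsoid inscribed in the grid (margin of one voxel)."""
    nx, ny, nz = grid_dims
    ii, jj, kk = np.indices(grid_dims, dtype=np.float64)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    rx, ry, rz = nx / 2 - 1, ny / 2 - 1, nz / 2 - 1
    return ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 + ((kk - cz) / rz) ** 2 <= 1.0


def _grid_affine(grid_dims, voxel_mm) -> np.ndarray:
    """Affine placing the grid center at the mm origin."""
    aff = np.eye(4)
    for ax in range(3):
        aff[ax, ax] = voxel_mm[ax]
        aff[ax, 3] = -voxel_mm[ax] * (grid_dims[ax] - 1) / 2
    return aff


def _seed_cube(grid_dims, voxel_mm, affine):
    """A 2x2x2-voxel seed cube near the grid center, described in mm.

    The cube center sits on a voxel corner so that the closed cube of edge
    2 x voxel size contains exactly eight voxel centers.
    """
    base = np.array([d // 2 - 1 for d in grid_dims])
    center_vox = base + 0.5  # corner between base and base+1
    center_mm = affine @ np.array([*center_vox, 1.0])
    edge_mm = 2.0 * float(min(voxel_mm))
    return tuple(center_mm[:3]), edge_mm, base


def _make_patterns(
    params: SimParams, mask: np.ndarray, seed_base: np.ndarray, rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Planted spatial maps: plateau-profiled multi-blob fields, pairwise
    corr < 0.5.

    Each pattern is a sum of three Gaussian blobs at random in-mask
    locations, peak-normalized and raised to a compressive exponent
    (``pattern_power``) so the profile plateaus like a cortical parcel
    rather than decaying as a sharp Gaussian peak; the seed cube is set to
    1 in every pattern.  Candidates too correlated with an accepted
    pattern are redrawn, which enforces the distinctness invariant by
    construction.
    """
    nx, ny, nz = params.grid_dims
    flat_mask = mask.ravel()
    in_mask_idx = np.flatnonzero(flat_mask)
    patterns: list[np.ndarray] = []
    seed_sl = tuple(slice(int(b), int(b) + 2) for b in seed_base)
    for _ in range(params.k_true):
        for _attempt in range(max_tries):
            vol = np.zeros(params.grid_dims)
            centers = in_mask_idx[rng.integers(0, in_mask_idx.size, size=3)]
            for c in centers:
                vol[np.unravel_index(c, params.grid_dims)] += 1.0
            vol = gaussian_filter(vol, sigma=params.pattern_sigma_vox, mode="constant")
            vol[~mask] = 0.0
            if vol.max() <= 0:
                continue
            vol = (vol / vol.max()) ** params.pattern_power
            vol[seed_sl] = 1.0
            ok = True
            v = vol[mask]
            for prev in patterns:
                p = prev[mask]
                r = np.corrcoef(v, p)[0, 1]
                if not np.isfinite(r) or abs(r) >= 0.5:
                    ok = False
                    break
            if ok:
                patterns.append(vol)
                break
        else:
            raise RuntimeError("could not place a sufficiently distinct pattern")
    return np.stack(patterns)


def _session_rng(seed: int, subject: int, condition: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject, condition)))


def generate_cohort(
    params: SimParams,
    gains: np.ndarray | None = None,
    condition_labels: tuple | None = None,
) -> tuple[list[BoldSession], list[np.ndarray], GroundTruth]:
    """Generate ``n_subjects x n_conditions`` sessions with planted CAPs.

    Parameters
    ----------
    params : SimParams
    gains : ndarray, shape (n_conditions, k_true), optional
        Non-negative amplitude multipliers per condition and pattern.
        Defaults to all ones (no condition effect).
    condition_labels : tuple of str, optional

    Returns
    -------
    sessions : list of BoldSession (subject-major order)
    motion : list of (n_frames, 6) motion-parameter arrays, aligned
    truth : GroundTruth
    """
    if gains is None:
        gains = np.ones((params.n_conditions, params.k_true))
    gains = np.asarray(gains, dtype=np.float64)
    if gains.shape != (params.n_conditions, params.k_true):
        raise ValueError(
            f"gains shape {gains.shape} does not match "
            f"(n_conditions, k_true) = {(params.n_conditions, params.k_true)}"
        )
    if (gains < 0).any():
        raise ValueError("condition gains must be non-negative")
    if condition_labels is None:
        condition_labels = tuple(
            DEFAULT_CONDITIONS[c] if c < len(DEFAULT_CONDITIONS) else f"cond-{c}"
            for c in range(params.n_conditions)
        )

    mask = _ellipsoid_mask(params.grid_dims)
    affine = _grid_affine(params.grid_dims, params.voxel_mm)
    seed_center_mm, seed_edge_mm, seed_base = _seed_cube(params.grid_dims, params.voxel_mm, affine)

    master = np.random.default_rng(np.random.SeedSequence(params.rng_seed, spawn_key=(0xCA9,)))
    patterns = _make_patterns(params, mask, seed_base, master)
    pat_mat = patterns[:, mask]  # (k, V)
    n_vox = pat_mat.shape[1]

    hrf = canonical_hrf(params.tr_seconds)
    hrf_peak_lag = int(np.argmax(hrf))
    t = params.n_frames
    t_norm = np.linspace(-1.0, 1.0, t)
    drift_basis = np.stack([t_norm, t_norm**2 - np.mean(t_norm**2)], axis=1)  # (t, 2)

    sessions: list[BoldSession] = []
    motion: list[np.ndarray] = []
    event_times: dict = {}
    drift_coeffs: dict = {}
    spike_frames: dict = {}

    for s in range(params.n_subjects):
        for c in range(params.n_conditions):
            rng = _session_rng(params.rng_seed, s, c)
            # --- events -------------------------------------------------
            is_event = rng.random(t) < params.event_rate
            w = gains[c]
            if w.sum() > 0:
                p = w / w.sum()
            else:  # fully suppressed condition: events still occur, flat choice
                p = np.full(params.k_true, 1.0 / params.k_true)
            pat_ids = rng.choice(params.k_true, size=t, p=p)
            ev = [(int(f), int(pat_ids[f])) for f in np.flatnonzero(is_event)]
            event_times[(s, c)] = ev
            # HRF-convolved train per pattern
            sig = np.zeros((t, n_vox))
            for j in range(params.k_true):
                train = np.zeros(t)
                for f, pid in ev:
                    if pid == j:
                        train[f] = 1.0
                reg = np.convolve(train, hrf)[:t]
                if reg.any():
                    sig += params.amplitude * gains[c, j] * np.outer(reg, pat_mat[j])
            # --- drift, noise, baseline ---------------------------------
            dc = rng.normal(0.0, params.drift_scale, size=(n_vox, 2))
            dc[:, 1] *= 0.5
            drift_coeffs[(s, c)] = dc
            sig += drift_basis @ dc.T
            if params.noise_sd > 0:
                # physiological-like noise: an i.i.d. thermal component plus a
                # spatially smooth component that survives spatial smoothing,
                # mixed so noise_spatial_frac of the variance is structured
                w_sm = np.sqrt(params.noise_spatial_frac)
                w_iid = np.sqrt(1.0 - params.noise_spatial_frac)
                eps = w_iid * rng.normal(size=(t, n_vox))
                if w_sm > 0:
                    field = rng.normal(size=(*params.grid_dims, t))
                    for i in range(t):
                        field[..., i] = gaussian_filter(
                            field[..., i], sigma=params.noise_spatial_sigma_vox,
                            mode="reflect",
                        )
                    sm = field[mask].T
                    sm /= sm.std()
                    eps += w_sm * sm
                eps *= params.noise_sd
                if params.ar1_rho:
                    for i in range(1, t):
                        eps[i] = params.ar1_rho * eps[i - 1] + np.sqrt(
                            1 - params.ar1_rho**2
                        ) * eps[i]
                sig += eps
            sig += params.baseline
            # --- motion spikes ------------------------------------------
            n_spk = rng.binomial(t - 1, params.spike_rate)
            spk = np.sort(rng.choice(np.arange(1, t), size=n_spk, replace=False))
            spike_frames[(s, c)] = [int(f) for f in spk]
            mp = np.empty((t, 6))
            mp[:, :3] = rng.normal(0.0, params.jitter_translation_mm, size=(t, 3))
            mp[:, 3:] = rng.normal(0.0, params.jitter_rotation_rad, size=(t, 3))
            for f in spk:
                axis = int(rng.integers(0, 3))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                mp[f:, axis] += sign * params.spike_translation_mm  # sustained offset
                blip = 1.0 if rng.random() < 0.5 else -1.0
                sig[f] += blip * params.spike_intensity_au  # one-frame DVARS blip
            data = np.zeros((*params.grid_dims, t))
            data[mask] = sig.T
            sessions.append(
                BoldSession(
                    data=data,
                    affine=affine,
                    mask=mask,
                    tr_seconds=params.tr_seconds,
                    subject_id=f"sub-{s + 1:02d}",
                    condition_label=condition_labels[c],
                )
            )
            motion.append(mp)

    truth = GroundTruth(
        patterns=patterns,
        event_times=event_times,
        condition_gains=gains,
        noise_sd=params.noise_sd,
        drift_coeffs=drift_coeffs,
        motion_spike_frames=spike_frames,
        mask=mask,
        affine=affine,
        seed_center_mm=seed_center_mm,
        seed_edge_mm=seed_edge_mm,
        condition_labels=condition_labels,
        hrf_peak_lag=hrf_peak_lag,
        rng_seed=params.rng_seed,
    )
    return sessions, motion, truth


def export_cohort(
    sessions: list[BoldSession],
    motion: list[np.ndarray],
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict:
    """Write one NIfTI + one motion TSV per session, pattern maps and a
    JSON manifest; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for sess, mp in zip(sessions, motion):
        stem = f"{sess.subject_id}_{sess.condition_label}"
        bold = f"{stem}_bold.nii.gz"
        mot = f"{stem}_motion.tsv"
        sess.save(out / bold)
        save_motion_params(mp, out / mot)
        entries.append(
            {
                "subject_id": sess.subject_id,
                "condition_label": sess.condition_label,
                "bold": bold,
                "motion": mot,
                "n_frames": sess.n_frames,
                "tr_seconds": sess.tr_seconds,
            }
        )
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(truth.mask.astype(np.uint8), truth.affine), str(out / "mask.nii.gz")
    )
    save_pattern_maps(truth.patterns, truth.affine, out / "ground_truth_patterns.nii.gz")
    manifest = {
        "sessions": entries,
        "mask": "mask.nii.gz",
        "patterns": "ground_truth_patterns.nii.gz",
        "seed": {
            "center_mm": [float(x) for x in truth.seed_center_mm],
            "edge_mm": float(truth.seed_edge_mm),
            "space_tag": "synthetic",
        },
        "condition_labels": list(truth.condition_labels),
        "condition_gains": truth.condition_gains.tolist(),
        "noise_sd": float(truth.noise_sd),
        "hrf_peak_lag": int(truth.hrf_peak_lag),
        "rng_seed": int(truth.rng_seed),
        "event_times": {f"{s},{c}": ev for (s, c), ev in truth.event_times.items()},
        "motion_spike_frames": {
            f"{s},{c}": fr for (s, c), fr in truth.motion_spike_frames.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_manifest(out_dir: str | Path) -> dict:
    with open(Path(out_dir) / "manifest.json") as fh:
        return json.load(fh)
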