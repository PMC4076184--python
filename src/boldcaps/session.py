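"""4D BOLD session container and NIfTI / TSV I/O.

A :class:`BoldSession` bundles one subject x one condition 4D time series
with its grid geometry (affine), brain mask and repetition time.  All
voxelwise pipeline stages operate on the 2D ``(t, n_in_mask_voxels)``
matrix view returned by :meth:`BoldSession.masked_timeseries`; out-of-mask
voxels are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass
class BoldSession:
    """One subject x one condition 4D BOLD run.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD signal in arbitrary units.
    affine : ndarray, shape (4, 4)
        Voxel-to-mm affine (NIfTI convention).
    mask : ndarray of bool, shape (x, y, z)
        Brain mask; analysis is restricted to in-mask voxels.
    tr_seconds : float
        Repetition time in seconds.
    subject_id, condition_label : str
        Identifiers carried through the pipeline.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    tr_seconds: float
    subject_id: str = "sub-00"
    condition_label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, t), got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial dims of data")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask.sum() < 1:
            raise ValueError("mask must contain at least one voxel")
        if self.n_frames < 10:
            raise ValueError(f"need at least 10 frames, got {self.n_frames}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def masked_timeseries(self) -> np.ndarray:
        """Return the in-mask data as a ``(t, n_voxels)`` matrix (copy)."""
        return np.ascontiguousarray(self.data[self.mask].T)

    def with_masked_timeseries(self, mat: np.ndarray) -> "BoldSession":
        """Return a new session whose in-mask voxels hold ``mat`` (t, n_voxels).

        Out-of-mask voxels are copied unchanged, so every stage built on this
        helper is mask-respecting by construction.
        """
        mat = np.asarray(mat, dtype=np.float64)
        if mat.shape != (self.n_frames, self.n_mask_voxels):
            raise ValueError(
                f"expected shape {(self.n_frames, self.n_mask_voxels)}, got {mat.shape}"
            )
        data = self.data.copy()
        data[self.mask] = mat.T
        return replace(self, data=data)

    def with_data(self, data: np.ndarray) -> "BoldSession":
        return replace(self, data=data)

    # ---- I/O -------------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_sizes_mm, self.tr_seconds))
        return img

    def save(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        nib.save(self.to_nifti(), str(path))
        if mask_path is not None:
            nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine), str(mask_path))

    @classmethod
    def load(
        cls,
        path: str | Path,
        mask_path: str | Path | None = None,
        tr_seconds: float | None = None,
        subject_id: str = "sub-00",
        condition_label: str = "unknown",
    ) -> "BoldSession":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        if mask_path is not None:
            mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0.5
        else:
            mask = np.ones(data.shape[:3], dtype=bool)
        if tr_seconds is None:
            zooms = img.header.get_zooms()
            tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(
            data=data,
            affine=img.affine,
            mask=mask,
            tr_seconds=tr_seconds,
            subject_id=subject_id,
            condition_label=condition_label,
        )


def save_pattern_maps(maps: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Save a (K, x, y, z) stack of spatial maps as one 4D NIfTI."""
    stack = np.moveaxis(np.asarray(maps, dtype=np.float32), 0, -1)
    nib.save(nib.Nifti1Image(stack, np.asarray(affine)), str(path))


def load_pattern_maps(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D NIfTI into a (K, x, y, z) array plus its affine."""
    img = nib.load(str(path))
    return np.moveaxis(np.asarray(img.get_fdata(), dtype=np.float64), -1, 0), img.affine


def save_motion_params(params: np.ndarray, path: str | Path) -> None:
    """Write a (t, 6) motion-parameter series as TSV (mm, mm, mm, rad, rad, rad)."""
    params = np.asarray(params, dtype=np.float64)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"motion params must be (t, 6), got {params.shape}")
    pd.DataFrame(params, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)


def load_motion_params(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV missing columns: {missing}")
    return df[MOTION_COLUMNS].to_numpy(dtype=np.float64)
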