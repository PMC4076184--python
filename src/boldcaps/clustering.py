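"""K-means clustering of supra-threshold frames into co-activation patterns.

Frames are compared by spatial similarity: each frame is centered and
unit-normalized before Euclidean k-means, which orders distances exactly
as 1 - Pearson correlation.  Two modes are supported:

* **free clustering** (:meth:`CapKMeans.fit`) — fit K centroids on a
  reference frame collection (best of ``n_restarts`` k-means++ runs,
  deterministic given ``random_state``);
* **fixed-centroid assignment** (:meth:`CapKMeans.predict`) — classify new
  frames against immutable centroids so cluster indices are comparable
  across experimental conditions.

CAPs themselves are arithmetic means of the *original* standardized frames
within each cluster (not the per-frame-normalized ones), so cap amplitude
keeps its BOLD-SD meaning; the occupancy-weighted mean of the K caps
therefore equals the grand mean of all clustered frames exactly — the
decomposition of a seed-correlation map into transient states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

METRIC_TAG = "centered-unit-euclidean"


class EmptyClusterWarning(UserWarning):
    """A cluster received no frames; its cap is all-zero with occupancy 0."""


def normalize_frames(X: np.ndarray) -> np.ndarray:
    """Center each row and scale it to unit L2 norm (flat rows become zero).

    Rows whose centered norm is at rounding level relative to the row's
    magnitude are treated as flat and mapped to zero, so a constant map
    never turns into a spurious uniform direction.
    """
    X = np.asarray(X, dtype=np.float64)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    flat = norms[:, 0] <= 1e-12 * (1.0 + np.abs(X).max(axis=1))
    Xc[flat] = 0.0
    norms[flat] = 1.0
    return Xc / norms


class CapKMeans(ClusterMixin, BaseEstimator):
    """K-means over spatial frames with a correlation-style metric.

    Parameters
    ----------
    n_clusters : int, default 8
        Number of CAPs (the analysis convention fixes K = 8).
    n_restarts : int, default 10
        k-means++ restarts; the best run by within-cluster sum of squares
        is kept.
    random_state : int, default 0
        Seed for initialization; fixed seeds make the fitted centroids a
        reproducible reference.

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters, n_voxels)
        Centroids in canonical form (centered, unit norm).
    labels_ : ndarray (n_frames,)
        Training-frame assignments.
    inertia_ : float
        Within-cluster sum of squares of the winning run (on normalized
        frames, against the un-renormalized cluster means).
    """

    def __init__(self, n_clusters: int = 8, n_restarts: int = 10, random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[0] < self.n_clusters:
            raise ValueError(
                f"cannot fit {self.n_clusters} clusters on {X.shape[0]} frames"
            )
        Xn = normalize_frames(X)
        km = KMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.n_restarts,
            random_state=self.random_state,
        ).fit(Xn)
        self.cluster_centers_ = normalize_frames(km.cluster_centers_)
        self.labels_ = km.labels_.astype(int)
        self.inertia_ = float(km.inertia_)
        self.fit_provenance_ = {
            "n_frames": int(X.shape[0]),
            "n_restarts": int(self.n_restarts),
            "random_state": int(self.random_state),
            "metric": METRIC_TAG,
        }
        return self

    def predict(self, X):
        """Nearest fixed centroid per frame; ties go to the lowest index.

        Centroids are never updated by prediction.
        """
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X)
        if X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError(
                f"frames have {X.shape[1]} voxels, centroids have "
                f"{self.cluster_centers_.shape[1]}"
            )
        d = cdist(normalize_frames(X), self.cluster_centers_)
        return np.argmin(d, axis=1)  # np.argmin returns the first minimum


@dataclass
class CentroidSet:
    """Serializable fixed reference centroids."""

    centroids: np.ndarray  # (k, n_voxels)
    metric_tag: str = METRIC_TAG
    fit_provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise ValueError("centroids must be a (k, n_voxels) array with k >= 1")
        for i in range(self.k):
            for j in range(i + 1, self.k):
                if np.array_equal(self.centroids[i], self.centroids[j]):
                    raise ValueError(f"centroids {i} and {j} are identical")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @classmethod
    def from_estimator(cls, est: CapKMeans) -> "CentroidSet":
        check_is_fitted(est, "cluster_centers_")
        return cls(
            centroids=est.cluster_centers_.copy(),
            metric_tag=METRIC_TAG,
            fit_provenance=dict(est.fit_provenance_),
        )

    def to_estimator(self) -> CapKMeans:
        est = CapKMeans(n_clusters=self.k)
        est.cluster_centers_ = self.centroids.copy()
        est.fit_provenance_ = dict(self.fit_provenance)
        return est


def fit_centroids(
    frames: np.ndarray, k: int = 8, n_restarts: int = 10, rng_seed: int = 0
) -> CentroidSet:
    """Free k-means over stacked point-process frames (reference fit)."""
    est = CapKMeans(n_clusters=k, n_restarts=n_restarts, random_state=rng_seed).fit(frames)
    return CentroidSet.from_estimator(est)


def assign_to_centroids(frames: np.ndarray, centroids: CentroidSet) -> np.ndarray:
    """Fixed-centroid assignment (no centroid update)."""
    return centroids.to_estimator().predict(frames)


@dataclass
class CapSet:
    """Per-condition co-activation patterns with occupancy counts."""

    caps: np.ndarray  # (k, n_voxels) mean maps
    occupancy: np.ndarray  # (k,) frame counts
    condition_label: str = "unknown"
    member_index: np.ndarray = None  # per-frame cluster label

    @property
    def k(self) -> int:
        return self.caps.shape[0]

    @property
    def n_frames(self) -> int:
        return int(self.occupancy.sum())

    def grand_mean(self) -> np.ndarray:
        """Occupancy-weighted mean of the caps (= grand mean of the frames)."""
        return (self.occupancy[:, None] * self.caps).sum(axis=0) / max(self.n_frames, 1)


def compute_caps(
    frames: np.ndarray, labels: np.ndarray, k: int, condition_label: str = "unknown"
) -> CapSet:
    """Average within-cluster frames into K caps.

    Empty clusters yield an all-zero cap with occupancy 0 and a warning.
    """
    frames = np.asarray(frames, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError("labels must lie in [0, k)")
    caps = np.zeros((k, frames.shape[1] if frames.ndim == 2 else 0))
    occ = np.zeros(k, dtype=int)
    for j in range(k):
        sel = labels == j
        occ[j] = int(sel.sum())
        if occ[j]:
            caps[j] = frames[sel].mean(axis=0)
    if (occ == 0).any():
        warnings.warn(
            f"{int((occ == 0).sum())} empty cluster(s): all-zero cap(s) reported",
            EmptyClusterWarning,
            stacklevel=2,
        )
    return CapSet(caps=caps, occupancy=occ, condition_label=condition_label,
                  member_index=labels)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two spatial maps (NaN if either is flat)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def match_and_compare(caps_a: CapSet, caps_b: CapSet) -> pd.DataFrame:
    """Index-by-index comparison of two cap sets sharing fixed centroids.

    Returns a table with the per-index spatial Pearson correlation and the
    occupancy difference; valid only when both sets were assigned against
    the same immutable centroids (which guarantees index correspondence).
    """
    if caps_a.k != caps_b.k:
        raise ValueError(f"cap-set sizes differ: {caps_a.k} vs {caps_b.k}")
    if caps_a.caps.shape[1] != caps_b.caps.shape[1]:
        raise ValueError("cap sets live in different voxel spaces")
    rows = []
    for j in range(caps_a.k):
        rows.append(
            {
                "cap_index": j,
                "correlation": spatial_correlation(caps_a.caps[j], caps_b.caps[j]),
                "occupancy_a": int(caps_a.occupancy[j]),
                "occupancy_b": int(caps_b.occupancy[j]),
                "occupancy_delta": int(caps_b.occupancy[j] - caps_a.occupancy[j]),
            }
        )
    return pd.DataFrame(rows)


def match_patterns_to_caps(patterns: np.ndarray, caps: np.ndarray) -> pd.DataFrame:
    """Best-matching cap (by spatial correlation) for each planted pattern."""
    rows = []
    for i, pat in enumerate(np.asarray(patterns, float)):
        corrs = [spatial_correlation(pat, cap) for cap in np.asarray(caps, float)]
        best = int(np.nanargmax(corrs))
        rows.append({"pattern": i, "best_cap": best, "correlation": corrs[best]})
    return pd.DataFrame(rows)
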