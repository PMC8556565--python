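"""Speckle-variance angiography.

Blood flow decorrelates the speckle pattern between repeated B-scans, so
the temporal variance of intensity highlights vessels.  A motion-robust
variant removes, per BM-scan, the frame whose exclusion lowers the mean
variance the most (residual bulk motion inflates variance globally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import OCTVolume

__all__ = [
    "AngioVolume",
    "VesselMask",
    "speckle_variance",
    "motion_robust_variance",
    "enface_projection",
    "vessel_mask",
]


@dataclass
class AngioVolume:
    """Temporal-variance volume ``(bscan, depth, aline)``.

    ``n_frames_used`` is the per-B-scan frame count that entered the
    variance; ``removed_frames`` the index dropped by the motion-robust
    estimator (None when no removal was applied).
    """

    variance: np.ndarray
    n_frames_used: np.ndarray
    removed_frames: np.ndarray | None = None


@dataclass
class VesselMask:
    """Binary en-face vessel map with the threshold that produced it."""

    mask: np.ndarray
    threshold: float


def speckle_variance(vol: OCTVolume) -> AngioVolume:
    """Per-voxel population variance (divisor N) across the repeat axis."""
    if vol.n_repeats < 2:
        raise ValueError("speckle variance requires at least 2 repeated frames")
    var = vol.data.var(axis=1, ddof=0)
    n_used = np.full(vol.n_bscans, vol.n_repeats, dtype=int)
    return AngioVolume(variance=var, n_frames_used=n_used)


def motion_robust_variance(vol: OCTVolume) -> AngioVolume:
    """Leave-one-out variance: drop the frame that inflates variance most.

    For each B-scan, the variance is evaluated over every subset omitting
    one frame; the subset with the lowest spatial-mean variance is kept
    (ties resolved by dropping the last frame).  The spatial mean of the
    result can only be lower than or equal to the full-set variance.
    """
    R = vol.n_repeats
    if R < 3:
        raise ValueError("motion-robust variance requires at least 3 frames")
    B = vol.n_bscans
    var = np.empty((B, vol.n_depth, vol.n_alines))
    removed = np.empty(B, dtype=int)
    for b in range(B):
        frames = vol.data[b]
        best_mean = np.inf
        best_var = None
        best_j = -1
        for j in range(R):
            subset = np.delete(frames, j, axis=0)
            v = subset.var(axis=0, ddof=0)
            m = v.mean()
            if m <= best_mean:  # ties -> larger j, i.e. drop the last frame
                best_mean, best_var, best_j = m, v, j
        var[b] = best_var
        removed[b] = best_j
    n_used = np.full(B, R - 1, dtype=int)
    return AngioVolume(variance=var, n_frames_used=n_used, removed_frames=removed)


def enface_projection(vol3d: np.ndarray, depth_range: tuple[int, int]) -> np.ndarray:
    """Mean over a depth window: ``(bscan, depth, aline)`` -> ``(bscan, aline)``.

    ``depth_range`` is a half-open ``[z0, z1)`` window.
    """
    z0, z1 = depth_range
    z0, z1 = max(int(z0), 0), min(int(z1), vol3d.shape[1])
    if z1 <= z0:
        raise ValueError(f"empty depth window {depth_range}")
    return vol3d[:, z0:z1, :].mean(axis=1)


def vessel_mask(enface: np.ndarray, k_sd: float = 2.0, min_area: int = 5) -> VesselMask:
    """Threshold an en-face map at mean + k_sd * SD, drop small components.

    Connected components (8-connectivity) smaller than ``min_area`` pixels
    are treated as noise and removed.
    """
    m = np.asarray(enface, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("en-face map must be finite")
    threshold = float(m.mean() + k_sd * m.std())
    mask = m > threshold
    if min_area > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        counts = np.bincount(labels.ravel())
        keep = counts >= min_area
        keep[0] = False
        mask = keep[labels]
    return VesselMask(mask=mask, threshold=threshold)
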