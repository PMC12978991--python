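"""Seed-to-whole-brain functional connectivity with Fisher z-transform.

For one contrast seed and one subject: average the time series over the
seed voxels, correlate that series with every in-mask voxel (Pearson),
and apply Fisher's z (atanh) for variance stabilization.  Correlations
are clipped to 1 - 1e-7 in magnitude before atanh so seed-internal voxels
(r == 1) stay finite; zero-variance voxels are flagged invalid rather
than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid
from .seeds import SeedMask

R_CLIP = 1.0 - 1e-7


class FCError(ValueError):
    pass


@dataclass
class FCMap:
    """One subject's Fisher-z seed connectivity volume."""

    subject_id: str
    contrast_id: str
    z: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)


def seed_timeseries(ts4d: np.ndarray, seed: SeedMask) -> np.ndarray:
    """Unweighted mean time series over the seed voxels (length T)."""
    ts4d = np.asarray(ts4d)
    if ts4d.ndim != 4:
        raise FCError(f"expected 4D data, got {ts4d.ndim}D")
    if seed.volume.shape != ts4d.shape[:3]:
        raise FCError(
            f"seed shape {seed.volume.shape} != data shape {ts4d.shape[:3]}"
        )
    idx = np.argwhere(seed.volume)
    if len(idx) == 0:
        raise FCError(f"contrast {seed.contrast_id!r}: empty seed")
    return np.asarray(
        ts4d[idx[:, 0], idx[:, 1], idx[:, 2], :], dtype=np.float64
    ).mean(axis=0)


def fc_zmap(
    ts4d: np.ndarray,
    seed: SeedMask,
    grid: VolumeGrid,
    subject_id: str = "",
) -> FCMap:
    """Fisher-z map of seed-mean vs every in-mask voxel.

    Zero-variance voxels are marked invalid (z set to 0 there); a
    zero-variance seed series is a hard error.
    """
    ts4d = np.asarray(ts4d, dtype=np.float64)
    if ts4d.shape[3] < 10:
        raise FCError(f"need T >= 10 timepoints, got {ts4d.shape[3]}")
    s = seed_timeseries(ts4d, seed)
    s = s - s.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise FCError(f"contrast {seed.contrast_id!r}: zero-variance seed series")
    flat = ts4d.reshape(-1, ts4d.shape[3])
    midx = grid.mask_indices()
    X = flat[midx, :].T  # T x V
    col_mean = X.mean(axis=0)
    X = X - col_mean
    norms = np.linalg.norm(X, axis=0)
    # relative tolerance: a constant series leaves round-off of order
    # eps * |mean| * sqrt(T) after centering, which is not real variance
    valid_v = norms > 1e-8 * np.sqrt(X.shape[0]) * (1.0 + np.abs(col_mean))
    r = np.zeros(X.shape[1])
    r[valid_v] = (s @ X[:, valid_v]) / (s_norm * norms[valid_v])
    z_masked = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z = np.zeros(grid.shape)
    valid = np.zeros(grid.shape, dtype=bool)
    z.ravel()[midx] = np.where(valid_v, z_masked, 0.0)
    valid.ravel()[midx] = valid_v
    return FCMap(
        subject_id=subject_id, contrast_id=seed.contrast_id, z=z, valid=valid
    )
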