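"""Contrast seed masks: unions of fixed-radius spheres on the grid.

Each contrast's reported peaks become one combined seed: a sphere of the
configured radius (default 4 mm) is drawn around every coordinate and the
spheres are merged.  Sphere membership is decided in mm space — a voxel
belongs to a sphere when the Euclidean distance from its *center* to the
focus is at most the radius (closed ball) — so anisotropic grids are
handled correctly and the ``<=`` boundary rule is explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid


class SeedError(ValueError):
    pass


@dataclass
class SeedMask:
    """Binary seed volume for one contrast."""

    contrast_id: str
    direction: str
    radius_mm: float
    volume: np.ndarray = field(repr=False)
    n_foci: int = 0

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())

    def flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.volume.ravel())


def sphere_voxels(
    center_mm: np.ndarray, radius_mm: float, grid: VolumeGrid
) -> np.ndarray:
    """(n, 3) indices of in-mask voxels whose centers lie within
    ``radius_mm`` of ``center_mm`` (closed ball, mm distances).

    A center whose bounding cube misses the grid entirely yields an empty
    set with a warning rather than an error.
    """
    if radius_mm <= 0:
        raise SeedError(f"radius must be positive, got {radius_mm}")
    center_mm = np.asarray(center_mm, dtype=float)
    cv = grid.mm_to_voxel(center_mm)
    # conservative per-axis half-width in voxels
    sizes = grid.voxel_sizes_mm
    half = np.ceil(radius_mm / sizes).astype(int) + 1
    lo = np.maximum(np.floor(cv).astype(int) - half, 0)
    hi = np.minimum(np.ceil(cv).astype(int) + half, np.asarray(grid.shape) - 1)
    if np.any(lo > hi):
        warnings.warn(
            f"focus at {center_mm.tolist()} mm lies outside the grid", stacklevel=2
        )
        return np.empty((0, 3), dtype=int)
    axes = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    cand = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d = np.linalg.norm(grid.voxel_to_mm(cand) - center_mm, axis=1)
    cand = cand[d <= radius_mm]
    keep = grid.brain_mask[cand[:, 0], cand[:, 1], cand[:, 2]]
    return cand[keep]


def build_seed(
    foci_mm: np.ndarray,
    radius_mm: float,
    grid: VolumeGrid,
    contrast_id: str = "",
    direction: str = "",
) -> SeedMask:
    """Union of per-focus spheres, clipped to the brain mask.

    A focus whose entire sphere falls outside the mask contributes nothing
    (warned); if the union is empty the contrast is unusable and a
    :class:`SeedError` names it.
    """
    foci_mm = np.atleast_2d(np.asarray(foci_mm, dtype=float))
    if len(foci_mm) == 0:
        raise SeedError(f"contrast {contrast_id!r}: no foci")
    volume = np.zeros(grid.shape, dtype=bool)
    for focus in foci_mm:
        vox = sphere_voxels(focus, radius_mm, grid)
        if len(vox) == 0:
            warnings.warn(
                f"contrast {contrast_id!r}: focus {focus.tolist()} contributes "
                "no in-mask voxels",
                stacklevel=2,
            )
            continue
        volume[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    if not volume.any():
        raise SeedError(
            f"contrast {contrast_id!r}: combined seed empty (all foci outside mask)"
        )
    return SeedMask(
        contrast_id=contrast_id,
        direction=direction,
        radius_mm=float(radius_mm),
        volume=volume,
        n_foci=len(foci_mm),
    )
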