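"""Reference sampling grid shared by every volume in a run.

All volumes in an analysis live on one :class:`VolumeGrid`: a voxel array
shape, a 4x4 affine mapping 0-based voxel indices to millimetre (RAS+)
coordinates, and a binary brain mask restricting which voxels take part in
statistics.  Millimetres are the public coordinate currency; voxel indices
are an internal detail exposed only where geometry demands it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridError(ValueError):
    """Raised for invalid grid definitions or grid mismatches."""


@dataclass(frozen=True)
class VolumeGrid:
    """Shape + affine + brain mask defining the common analysis space.

    Parameters
    ----------
    shape : tuple of int
        Voxel array shape (nx, ny, nz).
    affine : (4, 4) ndarray
        Voxel-index (0-based) to mm (RAS+) map; must be invertible.
    brain_mask : ndarray of bool, same shape
        Voxels participating in the analysis. Must be non-empty.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    brain_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GridError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise GridError("affine is singular")
        mask = np.asarray(self.brain_mask, dtype=bool)
        if mask.shape != shape:
            raise GridError(f"brain_mask shape {mask.shape} != grid shape {shape}")
        if not mask.any():
            raise GridError("brain_mask is empty")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "brain_mask", mask)

    # -- coordinate transforms -------------------------------------------

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) mm coordinates to continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    # -- derived geometry ------------------------------------------------

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_mask_voxels(self) -> int:
        return int(self.brain_mask.sum())

    def mask_indices(self) -> np.ndarray:
        """Flat (C-order) indices of in-mask voxels, in raster order."""
        return np.flatnonzero(self.brain_mask.ravel())

    def mask_centers_mm(self) -> np.ndarray:
        """(n_mask_voxels, 3) mm centers of in-mask voxels, raster order."""
        ijk = np.argwhere(self.brain_mask)
        return self.voxel_to_mm(ijk)

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    @classmethod
    def pseudo_mni(
        cls,
        shape: tuple[int, int, int] = (20, 24, 20),
        voxel_size_mm: float = 3.0,
        brain_mask: np.ndarray | None = None,
    ) -> "VolumeGrid":
        """Desk-scale RAS+ grid with the mm origin at the grid centre."""
        shape = tuple(int(s) for s in shape)
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
        if brain_mask is None:
            brain_mask = np.ones(shape, dtype=bool)
        return cls(shape=shape, affine=affine, brain_mask=brain_mask)


def require_same_grid(*grids: VolumeGrid) -> None:
    """Raise :class:`GridError` naming both affines on any mismatch."""
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise GridError(
                "grid mismatch: affine\n"
                f"{first.affine}\nvs\n{g.affine} (shapes {first.shape} vs {g.shape})"
            )
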